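import numpy as np
import pytest

from bustdm.io_profiles import ConcSample, InfusionEvent, TdmProfile
from bustdm.pkmodels import OneCptParams, TwoCptParams, conc_onecpt, conc_twocpt


@pytest.fixture
def std_dose() -> InfusionEvent:
    """100 mg over 120 min, q6h, dose 9 of 16 — a typical busulfan study."""
    return InfusionEvent(
        dose_amount_mg=100.0,
        infusion_duration_min=120.0,
        tau_min=360.0,
        dose_number=9,
        total_planned_doses=16,
    )


def make_profile(dose, times, concs, patient_id="P001", weight=25.0, excluded=None):
    excluded = excluded or [False] * len(times)
    samples = tuple(
        ConcSample(time_min=float(t), conc_mg_l=float(c), excluded=e)
        for t, c, e in zip(times, concs, excluded)
    )
    return TdmProfile(
        patient_id=patient_id, dosing_weight_kg=weight, dose=dose, samples=samples
    )


@pytest.fixture
def onecpt_profile(std_dose):
    """Noise-free one-compartment profile on a dense schedule."""
    params = OneCptParams(clearance_l_min=0.25, volume_l=50.0)
    t = np.array([135.0, 150.0, 180.0, 240.0, 300.0, 360.0])
    c = conc_onecpt(t, params, std_dose)
    return make_profile(std_dose, t, c), params


@pytest.fixture
def twocpt_profile(std_dose):
    """Noise-free two-compartment profile with a clear distribution phase."""
    params = TwoCptParams(volume_v1_l=20.0, k10=0.012, k12=0.04, k21=0.01)
    t = np.array([125.0, 130.0, 135.0, 150.0, 165.0, 180.0, 240.0, 300.0, 360.0])
    c = conc_twocpt(t, params, std_dose)
    return make_profile(std_dose, t, c), params
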