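"""Exposure prediction and target-driven dose recommendation.

Under linear kinetics at steady state the per-dose exposure identities are
algebraic: ``AUC_tau = dose/CL`` and ``Cavg,ss = dose/(CL*tau)``, so hitting
a clinician-specified target is a matter of inverting them.  Three target
kinds are supported: AUC per dose, average steady-state concentration, and
cumulative AUC over the whole course given the dose number at which the
regimen changes.  Rounding what-ifs report the exposures at grid-rounded
doses so the prescriber can see the cost of a convenient dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import AnalysisConfig, DEFAULT_CONFIG

TARGET_KINDS = ("auc_per_dose", "cavg_ss", "cumulative_auc")


class TargetExceededError(ValueError):
    """Cumulative target already exceeded by the doses given so far."""


@dataclass(frozen=True)
class TherapeuticTarget:
    """Clinician-specified exposure target in canonical units.

    ``kind`` is one of ``auc_per_dose`` / ``cumulative_auc`` (mg*min/L) or
    ``cavg_ss`` (mg/L).  ``units_in`` records the unit string the value was
    originally entered in, for display.
    """

    kind: str
    value: float
    units_in: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TARGET_KINDS:
            raise ValueError(f"target kind must be one of {TARGET_KINDS}, got {self.kind!r}")
        if self.value <= 0:
            raise ValueError(f"target value must be > 0, got {self.value}")


@dataclass(frozen=True)
class Regimen:
    """Dosing course bookkeeping for course-level simulations.

    Doses 1..(change_at-1) are (or were) given at ``current_dose_mg``;
    doses change_at..total_doses would be given at a candidate new dose.
    """

    current_dose_mg: float
    tau_min: float
    change_at_dose: int
    total_doses: int

    def __post_init__(self) -> None:
        if self.current_dose_mg <= 0 or self.tau_min <= 0:
            raise ValueError("current_dose_mg and tau_min must be > 0")
        if not 1 <= self.change_at_dose <= self.total_doses:
            raise ValueError(
                f"change_at_dose {self.change_at_dose} outside 1..{self.total_doses}"
            )

    @property
    def n_remaining(self) -> int:
        return self.total_doses - self.change_at_dose + 1

    @property
    def n_at_current(self) -> int:
        return self.change_at_dose - 1


@dataclass(frozen=True)
class ExposureSummary:
    auc_per_dose_mg_min_l: float
    cavg_ss_mg_l: float
    cumulative_auc_mg_min_l: float | None = None


@dataclass(frozen=True)
class DoseRecommendation:
    current_dose_mg: float
    recommended_dose_mg: float
    change_at_dose: int
    total_doses: int
    clearance_l_min: float
    target: TherapeuticTarget
    predicted: ExposureSummary
    rounded_variants: tuple[tuple[float, ExposureSummary], ...]


def predict_exposure(cl_l_min: float, dose_mg: float, tau_min: float) -> ExposureSummary:
    """Per-dose steady-state exposures at a given clearance and dose."""
    if cl_l_min <= 0 or dose_mg <= 0 or tau_min <= 0:
        raise ValueError("CL, dose and tau must all be > 0")
    auc = dose_mg / cl_l_min
    return ExposureSummary(auc_per_dose_mg_min_l=auc, cavg_ss_mg_l=auc / tau_min)


def exposure_for_dose(
    cl_l_min: float, trial_dose_mg: float, regimen: Regimen
) -> ExposureSummary:
    """Exposure summary for a trial dose, including course cumulative AUC.

    The cumulative AUC sums per-dose AUCs over the whole course: doses
    before the change at the current dose, the remainder at the trial dose.
    """
    per = predict_exposure(cl_l_min, trial_dose_mg, regimen.tau_min)
    cumulative = (
        regimen.n_at_current * regimen.current_dose_mg
        + regimen.n_remaining * trial_dose_mg
    ) / cl_l_min
    return ExposureSummary(
        auc_per_dose_mg_min_l=per.auc_per_dose_mg_min_l,
        cavg_ss_mg_l=per.cavg_ss_mg_l,
        cumulative_auc_mg_min_l=cumulative,
    )


def _dose_for_target(cl: float, target: TherapeuticTarget, regimen: Regimen) -> float:
    if target.kind == "auc_per_dose":
        return cl * target.value
    if target.kind == "cavg_ss":
        return cl * target.value * regimen.tau_min
    # cumulative_auc: remaining doses must supply what the earlier ones did not
    remaining_auc = target.value - regimen.n_at_current * regimen.current_dose_mg / cl
    if remaining_auc <= 0:
        raise TargetExceededError(
            f"cumulative AUC target {target.value:g} mg*min/L already exceeded by the "
            f"{regimen.n_at_current} dose(s) at {regimen.current_dose_mg:g} mg"
        )
    return cl * remaining_auc / regimen.n_remaining


def recommend_dose(
    cl_l_min: float,
    target: TherapeuticTarget,
    regimen: Regimen,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> DoseRecommendation:
    """Dose that meets the target from the change point onward.

    The recommendation inverts the steady-state identities exactly, then
    reports rounding what-ifs on the configured grid (default 5 mg): the
    floor and ceiling doses with their full exposure summaries.
    """
    if cl_l_min <= 0:
        raise ValueError("clearance must be > 0")
    dose = _dose_for_target(cl_l_min, target, regimen)

    grid = config.dose_rounding_grid_mg
    lo = math.floor(dose / grid) * grid
    hi = math.ceil(dose / grid) * grid
    variants = []
    for d in dict.fromkeys((lo, hi)):  # dedupe when dose is on-grid
        if d > 0:
            variants.append((float(d), exposure_for_dose(cl_l_min, float(d), regimen)))

    return DoseRecommendation(
        current_dose_mg=regimen.current_dose_mg,
        recommended_dose_mg=dose,
        change_at_dose=regimen.change_at_dose,
        total_doses=regimen.total_doses,
        clearance_l_min=cl_l_min,
        target=target,
        predicted=exposure_for_dose(cl_l_min, dose, regimen),
        rounded_variants=tuple(variants),
    )


# --------------------------------------------------------------------------
# target unit conversion

_AUC_UNIT_FACTORS = {
    "mg*min/l": 1.0,
    "mg·min/l": 1.0,
    "mg.min/l": 1.0,
    "mg*h/l": 60.0,
    "mg·h/l": 60.0,
    "mg.h/l": 60.0,
}


def target_from_user_units(
    kind: str,
    value: float,
    units: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> TherapeuticTarget:
    """Build a target from clinician-entered units.

    AUC targets accept mg*min/L, mg*h/L, uM*min and uM*h (micromolar units
    via the configured molar mass); concentration targets accept mg/L and
    derived mass/molar units.  Conversion is exact and invertible.
    """
    key = units.strip().lower().replace("μ", "µ").replace("um", "µm")
    mm = config.molar_mass_g_mol
    if kind in ("auc_per_dose", "cumulative_auc"):
        if key in _AUC_UNIT_FACTORS:
            canonical = value * _AUC_UNIT_FACTORS[key]
        elif key in ("µm*min", "µmol*min/l", "µm·min"):
            canonical = value * mm * 1e-3
        elif key in ("µm*h", "µmol*h/l", "µm·h"):
            canonical = value * mm * 1e-3 * 60.0
        else:
            raise ValueError(f"unknown AUC unit {units!r}")
    elif kind == "cavg_ss":
        if key in ("mg/l", "µg/ml"):
            canonical = value
        elif key in ("ng/ml",):
            canonical = value * 1e-3
        elif key in ("µm", "µmol/l"):
            canonical = value * mm * 1e-3
        else:
            raise ValueError(f"unknown concentration unit {units!r}")
    else:
        raise ValueError(f"target kind must be one of {TARGET_KINDS}, got {kind!r}")
    return TherapeuticTarget(kind=kind, value=canonical, units_in=units)
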