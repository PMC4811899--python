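"""Curve stripping, weighted LM fitting, and nested model selection."""

import numpy as np
import pytest

from bustdm.config import AnalysisConfig
from bustdm.estimation import (
    AnalysisImpossibleError,
    ModelChoice,
    StrippingError,
    fit_model,
    override_route,
    select_model,
    strip_estimates,
)
from bustdm.io_profiles import ConcSample, InfusionEvent, TdmProfile
from bustdm.pkmodels import OneCptParams, TwoCptParams, conc_onecpt, conc_twocpt
from bustdm.synthgen import PopulationModel, simulate_cohort

from conftest import make_profile


def biexp_profile(dose, a, alpha, b, beta, t_post):
    """Post-infusion biexponential observations at offsets t_post from T_inf."""
    t_post = np.asarray(t_post, dtype=float)
    c = a * np.exp(-alpha * t_post) + b * np.exp(-beta * t_post)
    t = dose.infusion_duration_min + t_post
    return make_profile(dose, t, c)


class TestStripping:
    def test_exact_monoexponential_recovered(self, std_dose):
        prof = biexp_profile(std_dose, 0.0, 1.0, 5.0, 0.01, [0, 60, 120, 240])
        est = strip_estimates(prof)
        assert est.terminal_b_mg_l == pytest.approx(5.0, rel=1e-10)
        assert est.terminal_lambda == pytest.approx(0.01, rel=1e-10)
        assert est.terminal_r2 == pytest.approx(1.0)
        assert not est.has_two_exp_candidate

    def test_biexponential_within_stated_tolerances(self, std_dose):
        prof = biexp_profile(
            std_dose, 10.0, 0.05, 2.0, 0.005, [0, 15, 30, 60, 120, 240, 360]
        )
        est = strip_estimates(prof)
        assert est.has_two_exp_candidate
        assert est.terminal_lambda == pytest.approx(0.005, rel=0.02)
        assert est.terminal_b_mg_l == pytest.approx(2.0, rel=0.05)
        assert est.residual_alpha == pytest.approx(0.05, rel=0.15)

    def test_no_positive_residuals_means_no_second_phase(self, std_dose):
        prof = biexp_profile(std_dose, 0.0, 1.0, 5.0, 0.01, [0, 30, 60, 120, 240])
        assert not strip_estimates(prof).has_two_exp_candidate

    def test_too_few_points_rejected(self, std_dose):
        prof = make_profile(std_dose, [135, 240], [4.0, 2.0])
        with pytest.raises(StrippingError):
            strip_estimates(prof)

    def test_rising_terminal_rejected(self, std_dose):
        prof = make_profile(std_dose, [135, 240, 360], [1.0, 2.0, 4.0])
        with pytest.raises(StrippingError):
            strip_estimates(prof)


class TestFitModel:
    def test_exact_onecpt_recovery(self, onecpt_profile):
        prof, truth = onecpt_profile
        fit = fit_model(prof, 1, strip_estimates(prof))
        assert fit.converged
        assert fit.params.clearance_l_min == pytest.approx(truth.clearance_l_min, rel=1e-6)
        assert fit.params.volume_l == pytest.approx(truth.volume_l, rel=1e-6)
        assert fit.weighted_ss < 1e-16

    def test_exact_twocpt_recovery(self, twocpt_profile):
        prof, truth = twocpt_profile
        fit = fit_model(prof, 2, strip_estimates(prof))
        assert fit.converged
        for name in ("volume_v1_l", "k10", "k12", "k21"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-6
            )

    def test_fit_is_deterministic(self, onecpt_profile):
        prof, _ = onecpt_profile
        est = strip_estimates(prof)
        assert fit_model(prof, 1, est) == fit_model(prof, 1, est)

    def test_fit_invariant_to_sample_order(self, onecpt_profile):
        prof, _ = onecpt_profile
        shuffled = TdmProfile(
            prof.patient_id, prof.dosing_weight_kg, prof.dose,
            tuple(reversed(prof.samples)),
        )
        a = fit_model(prof, 1, strip_estimates(prof))
        b = fit_model(shuffled, 1, strip_estimates(shuffled))
        assert a.params == b.params

    def test_predictions_align_with_included_samples(self, onecpt_profile):
        prof, _ = onecpt_profile
        fit = fit_model(prof, 1, strip_estimates(prof))
        assert len(fit.predictions_mg_l) == len(prof.included_samples)

    def test_cv_reported_on_macro_scale(self, onecpt_profile):
        prof, _ = onecpt_profile
        fit = fit_model(prof, 1, strip_estimates(prof))
        assert len(fit.param_cv_pct) == 2  # (B, lambda)
        assert all(cv >= 0 for cv in fit.param_cv_pct)

    def test_stochastic_recovery_rate(self, std_dose):
        """With 10% proportional noise, CL within +/-15% in >=90% of fits."""
        pop = PopulationModel(
            noise_prop_frac=0.10, noise_add_sd_mg_l=0.0, two_cpt_fraction=0.0,
            schedule_min=(135.0, 150.0, 180.0, 240.0, 300.0, 360.0),
        )
        cohort = simulate_cohort(pop, 200, 20)
        ok = 0
        for sim in cohort:
            fit = fit_model(sim.profile, 1, strip_estimates(sim.profile))
            if abs(fit.clearance_l_min / sim.true_clearance_l_min - 1) <= 0.15:
                ok += 1
        assert ok / len(cohort) >= 0.90


class TestSelectModel:
    def test_noise_free_monoexponential_routes_1cpt(self, onecpt_profile):
        prof, _ = onecpt_profile
        choice = select_model(prof)
        assert choice.route == "compartmental_1"
        assert choice.fit is not None and choice.fit.model_order == 1

    def test_noise_free_biexponential_routes_2cpt(self, twocpt_profile):
        prof, _ = twocpt_profile
        choice = select_model(prof)
        assert choice.route == "compartmental_2"
        assert "two_compartment_accepted" in choice.reason_codes

    def test_sparse_profile_skips_2cpt(self, std_dose):
        # m=4 < 5: one-compartment only, regardless of kinetics
        params = TwoCptParams(20.0, 0.012, 0.04, 0.01)
        t = np.array([135.0, 180.0, 240.0, 360.0])
        prof = make_profile(std_dose, t, conc_twocpt(t, params, std_dose))
        choice = select_model(prof)
        assert choice.route == "compartmental_1"
        assert "few_post_infusion_points" in choice.reason_codes

    def test_too_few_points_is_analysis_impossible(self, std_dose):
        prof = make_profile(std_dose, [135.0, 240.0], [4.0, 2.0])
        with pytest.raises(AnalysisImpossibleError):
            select_model(prof)

    def test_nca_fallback_always_carries_reason(self):
        with pytest.raises(ValueError):
            ModelChoice(route="nca_fallback", reason_codes=())


class TestOverrideRoute:
    def test_override_to_nca(self, onecpt_profile):
        prof, _ = onecpt_profile
        choice = override_route(select_model(prof), "nca", prof)
        assert choice.route == "nca_fallback"
        assert "user_override" in choice.reason_codes

    def test_override_to_current_route_appends_reason_only(self, onecpt_profile):
        prof, _ = onecpt_profile
        base = select_model(prof)
        same = override_route(base, "compartmental", prof)
        assert same.route == base.route
        assert same.fit == base.fit
        assert same.reason_codes == base.reason_codes + ("user_override",)

    def test_override_to_compartmental_needs_computable_fit(self, std_dose):
        prof = make_profile(std_dose, [135.0, 240.0, 360.0], [1.0, 2.0, 4.0])
        choice = ModelChoice(route="nca_fallback", reason_codes=("stripping_failed",))
        with pytest.raises(StrippingError):
            override_route(choice, "compartmental", prof)
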