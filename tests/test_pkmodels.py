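"""Closed-form model equations against independent oracles and identities."""

import math

import numpy as np
import pytest

from bustdm.io_profiles import InfusionEvent
from bustdm.pkmodels import (
    DegenerateModelError,
    MacroConstants,
    ModelDomainError,
    OneCptParams,
    TwoCptParams,
    conc_onecpt,
    conc_twocpt,
    derived_params,
    macro_from_micro,
    micro_from_macro,
)
from bustdm.synthgen import ode_oracle


@pytest.fixture
def dose():
    return InfusionEvent(dose_amount_mg=100.0, infusion_duration_min=120.0, tau_min=360.0)


class TestOneCpt:
    def test_zero_at_time_zero(self, dose):
        p = OneCptParams(0.25, 50.0)
        assert conc_onecpt(0.0, p, dose) == 0.0

    def test_worked_end_of_infusion_value(self, dose):
        # R0/CL * (1 - exp(-k*120)) with R0=0.8333 mg/min, k=0.005/min
        p = OneCptParams(0.25, 50.0)
        assert conc_onecpt(120.0, p, dose) == pytest.approx(1.504, abs=5e-4)

    def test_infinite_infusion_plateau(self):
        long_dose = InfusionEvent(100.0, 1e7 - 1, 1e7)
        p = OneCptParams(0.25, 50.0)
        r0_over_cl = long_dose.infusion_rate_mg_min / 0.25
        assert conc_onecpt(5e6, p, long_dose) == pytest.approx(r0_over_cl, rel=1e-9)

    def test_negative_time_rejected(self, dose):
        with pytest.raises(ModelDomainError):
            conc_onecpt(-1.0, OneCptParams(0.25, 50.0), dose)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ModelDomainError):
            OneCptParams(0.0, 50.0)


class TestTwoCpt:
    def test_zero_at_time_zero(self, dose):
        p = TwoCptParams(20.0, 0.012, 0.04, 0.01)
        assert conc_twocpt(0.0, p, dose) == 0.0

    def test_reduces_to_onecpt_in_limit(self, dose):
        p1 = OneCptParams(0.25, 50.0)
        p2 = TwoCptParams(50.0, p1.k_elim, 1e-12, 1e-12)
        t = np.array([30.0, 120.0, 180.0, 360.0])
        np.testing.assert_allclose(
            conc_twocpt(t, p2, dose), conc_onecpt(t, p1, dose), rtol=1e-4
        )

    def test_degenerate_exponents_rejected(self):
        # k12 -> 0 with k10 == k21 gives a repeated root
        with pytest.raises(DegenerateModelError):
            macro_from_micro(TwoCptParams(20.0, 1.0, 1e-20, 1.0))


class TestMacroMicro:
    def test_worked_quadratic_roots(self):
        macro = macro_from_micro(TwoCptParams(10.0, 0.1, 0.05, 0.05))
        assert macro.alpha == pytest.approx(0.17071, abs=1e-5)
        assert macro.beta == pytest.approx(0.02929, abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_vieta_identities(self, seed):
        rng = np.random.default_rng(seed)
        k10, k12, k21 = np.exp(rng.uniform(np.log(1e-3), np.log(0.5), 3))
        p = TwoCptParams(10.0, k10, k12, k21)
        m = macro_from_micro(p)
        assert m.alpha * m.beta == pytest.approx(k10 * k21, rel=1e-12)
        assert m.alpha + m.beta == pytest.approx(k10 + k12 + k21, rel=1e-12)

    def test_exponents_match_rate_matrix_eigenvalues(self):
        p = TwoCptParams(15.0, 0.02, 0.07, 0.015)
        m = macro_from_micro(p)
        a = np.array([[-(p.k10 + p.k12), p.k21], [p.k12, -p.k21]])
        eig = np.sort(-np.linalg.eigvals(a))
        assert m.beta == pytest.approx(eig[0], rel=1e-10)
        assert m.alpha == pytest.approx(eig[1], rel=1e-10)

    def test_limiting_case_small_exchange(self):
        m = macro_from_micro(TwoCptParams(10.0, 0.1, 1e-9, 1e-9))
        assert m.alpha == pytest.approx(0.1, rel=1e-6)
        assert m.beta < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_micro_macro_round_trip(self, seed):
        rng = np.random.default_rng(100 + seed)
        k10, k12, k21 = np.exp(rng.uniform(np.log(1e-3), np.log(0.3), 3))
        p = TwoCptParams(12.0, k10, k12, k21)
        m = macro_from_micro(p)
        back = micro_from_macro(m.coeff_a, m.coeff_b, m.alpha, m.beta)
        assert back.volume_v1_l == pytest.approx(p.volume_v1_l, rel=1e-10)
        assert back.k10 == pytest.approx(p.k10, rel=1e-10)
        assert back.k12 == pytest.approx(p.k12, rel=1e-9)
        assert back.k21 == pytest.approx(p.k21, rel=1e-10)


class TestDerivedParams:
    def test_auc_identity(self, dose):
        d = derived_params(OneCptParams(0.25, 50.0), dose)
        assert d.auc_0_inf_mg_min_l == pytest.approx(400.0)
        assert d.cavg_ss_mg_l == pytest.approx(400.0 / 360.0)

    def test_terminal_half_life(self, dose):
        d = derived_params(OneCptParams(0.25, 50.0), dose)
        assert d.terminal_half_life_min == pytest.approx(math.log(2) / 0.005)

    @pytest.mark.parametrize(
        "params",
        [OneCptParams(0.25, 50.0), TwoCptParams(20.0, 0.012, 0.04, 0.01)],
        ids=["1cpt", "2cpt"],
    )
    def test_quadrature_matches_dose_over_cl(self, params, dose):
        """Numerical integral of C(t) to effective infinity equals dose/CL."""
        from scipy.integrate import quad

        fn = conc_onecpt if isinstance(params, OneCptParams) else conc_twocpt
        integral, _ = quad(
            lambda t: float(fn(t, params, dose)), 0, 2e5,
            points=[dose.infusion_duration_min], limit=500,
        )
        expected = dose.dose_amount_mg / params.clearance_l_min
        assert integral == pytest.approx(expected, rel=1e-3)


class TestStructuralProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_continuity_nonneg_and_linearity(self, seed, dose):
        rng = np.random.default_rng(seed)
        if seed % 2:
            k10, k12, k21 = np.exp(rng.uniform(np.log(5e-3), np.log(0.2), 3))
            params = TwoCptParams(float(rng.uniform(5, 50)), k10, k12, k21)
            fn = conc_twocpt
        else:
            params = OneCptParams(float(rng.uniform(0.05, 0.5)), float(rng.uniform(10, 80)))
            fn = conc_onecpt
        t_inf = dose.infusion_duration_min
        left = fn(t_inf - 1e-9, params, dose)
        right = fn(t_inf + 1e-9, params, dose)
        assert abs(left - right) < 1e-6 * fn(t_inf, params, dose)

        t = rng.uniform(0, 720, 50)
        c = fn(t, params, dose)
        assert np.all(c >= 0)

        double = InfusionEvent(2 * dose.dose_amount_mg, t_inf, dose.tau_min)
        np.testing.assert_allclose(fn(t, params, double), 2 * c, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_ode_oracle_equivalence(self, seed, dose):
        """Closed forms agree with tight-tolerance numerical integration."""
        rng = np.random.default_rng(1000 + seed)
        t = np.sort(rng.uniform(1.0, 720.0, 25))
        if seed % 2:
            k10, k12, k21 = np.exp(rng.uniform(np.log(5e-3), np.log(0.2), 3))
            params = TwoCptParams(float(rng.uniform(5, 50)), k10, k12, k21)
            c = conc_twocpt(t, params, dose)
        else:
            params = OneCptParams(float(rng.uniform(0.05, 0.5)), float(rng.uniform(10, 80)))
            c = conc_onecpt(t, params, dose)
        oracle = ode_oracle(params, dose, t)
        np.testing.assert_allclose(c, oracle, rtol=1e-6)
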