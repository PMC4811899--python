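"""Closed-form concentration-time functions for IV-infusion PK models.

One- and two-compartment models with zero-order (constant-rate) infusion
input and first-order elimination.  The two-compartment model is carried in
micro-constant form (V1, k10, k12, k21); the macro constants — the
coefficients and exponents of the biexponential disposition function — are
derived from it, since fit-quality scoring needs their coefficients of
variation.

All concentrations are mg/L, times minutes, volumes litres, rate constants
1/min.  Every function here is pure and vectorized over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .io_profiles import InfusionEvent

LN2 = math.log(2.0)


class ModelDomainError(ValueError):
    """Raised for parameter values outside the model's domain."""


class DegenerateModelError(ModelDomainError):
    """Two-compartment exponents coincide; use the one-compartment model."""


@dataclass(frozen=True)
class OneCptParams:
    """One-compartment parameters: clearance and volume of distribution."""

    clearance_l_min: float
    volume_l: float

    def __post_init__(self) -> None:
        if self.clearance_l_min <= 0 or self.volume_l <= 0:
            raise ModelDomainError(
                f"CL and V must be > 0 (got CL={self.clearance_l_min}, V={self.volume_l})"
            )

    @property
    def k_elim(self) -> float:
        """First-order elimination rate constant k = CL/V (1/min)."""
        return self.clearance_l_min / self.volume_l


@dataclass(frozen=True)
class TwoCptParams:
    """Two-compartment micro constants: central volume and rate constants.

    k10 eliminates from the central compartment; k12/k21 exchange with the
    peripheral compartment.  Clearance is V1*k10.
    """

    volume_v1_l: float
    k10: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        vals = (self.volume_v1_l, self.k10, self.k12, self.k21)
        if any(v <= 0 for v in vals):
            raise ModelDomainError(f"all two-compartment parameters must be > 0, got {vals}")

    @property
    def clearance_l_min(self) -> float:
        return self.volume_v1_l * self.k10


@dataclass(frozen=True)
class MacroConstants:
    """Biexponential disposition constants for a unit IV bolus.

    The unit-bolus concentration is ``A*exp(-alpha*t) + B*exp(-beta*t)``
    with A, B in (mg/L)/mg and alpha > beta > 0 in 1/min.  They satisfy
    alpha*beta = k10*k21 and alpha+beta = k10+k12+k21.
    """

    coeff_a: float
    coeff_b: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ModelDomainError(
                f"exponents must satisfy alpha > beta > 0, got alpha={self.alpha}, beta={self.beta}"
            )


@dataclass(frozen=True)
class DerivedPK:
    """Clinically-reported quantities derived from a fitted model."""

    clearance_l_min: float
    vss_l: float
    terminal_half_life_min: float
    auc_0_inf_mg_min_l: float
    cavg_ss_mg_l: float


# --------------------------------------------------------------------------
# concentration-time functions

def _infusion_response(
    t: NDArray[np.float64], lam: float, t_inf: float
) -> NDArray[np.float64]:
    """Unit-rate infusion response for one exponential mode.

    Integral of exp(-lam*(t-s)) over active-infusion times s; equals
    (1 - exp(-lam*t))/lam during infusion and the superposed start/stop
    difference afterwards.
    """
    t = np.asarray(t, dtype=float)
    during = -np.expm1(-lam * np.minimum(t, t_inf)) / lam
    after = np.exp(-lam * np.clip(t - t_inf, 0.0, None))
    return during * after


def conc_onecpt(
    t: ArrayLike, params: OneCptParams, dose: InfusionEvent
) -> NDArray[np.float64]:
    """One-compartment infusion concentration C(t) in mg/L.

    During infusion ``C(t) = (R0/CL)(1 - exp(-k t))``; afterwards the
    concentration at end of infusion declines monoexponentially.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ModelDomainError("time must be >= 0")
    r0 = dose.infusion_rate_mg_min
    k = params.k_elim
    c = (r0 / params.volume_l) * _infusion_response(t_arr, k, dose.infusion_duration_min)
    return c if t_arr.ndim else float(c)  # type: ignore[return-value]


def conc_twocpt(
    t: ArrayLike, params: TwoCptParams, dose: InfusionEvent
) -> NDArray[np.float64]:
    """Two-compartment infusion concentration C(t) in mg/L.

    Built by convolving the biexponential unit-impulse response with the
    zero-order input, so it is continuous at the end of infusion by
    construction and reduces to the one-compartment form as k12, k21 -> 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ModelDomainError("time must be >= 0")
    macro = macro_from_micro(params)
    r0 = dose.infusion_rate_mg_min
    t_inf = dose.infusion_duration_min
    c = r0 * (
        macro.coeff_a * _infusion_response(t_arr, macro.alpha, t_inf)
        + macro.coeff_b * _infusion_response(t_arr, macro.beta, t_inf)
    )
    return c if t_arr.ndim else float(c)  # type: ignore[return-value]


def macro_from_micro(params: TwoCptParams) -> MacroConstants:
    """Hybrid macro constants (A, B, alpha, beta) from micro constants.

    alpha and beta are the roots of ``s^2 - (k10+k12+k21) s + k10 k21 = 0``
    (equivalently the negated eigenvalues of the 2x2 rate matrix), and A, B
    come from the partial-fraction expansion of the central-compartment
    transfer function for a unit bolus.
    """
    k10, k12, k21 = params.k10, params.k12, params.k21
    if not all(math.isfinite(v) for v in (params.volume_v1_l, k10, k12, k21)):
        raise ModelDomainError("non-finite two-compartment parameters")
    s = k10 + k12 + k21
    p = k10 * k21
    disc = s * s - 4.0 * p
    if disc <= 0:
        raise DegenerateModelError(
            "repeated or complex exponents (discriminant <= 0); "
            "fit a one-compartment model instead"
        )
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    v1 = params.volume_v1_l
    coeff_a = (alpha - k21) / (v1 * (alpha - beta))
    coeff_b = (k21 - beta) / (v1 * (alpha - beta))
    return MacroConstants(coeff_a=coeff_a, coeff_b=coeff_b, alpha=alpha, beta=beta)


def micro_from_macro(
    coeff_a: float, coeff_b: float, alpha: float, beta: float
) -> TwoCptParams:
    """Invert unit-bolus macro constants back to micro constants.

    Standard identities: ``V1 = 1/(A+B)``, ``k21 = (A beta + B alpha)/(A+B)``,
    ``k10 = alpha beta / k21``, ``k12 = alpha + beta - k10 - k21``.
    """
    if min(coeff_a, coeff_b) <= 0 or not alpha > beta > 0:
        raise ModelDomainError("macro constants must satisfy A,B > 0 and alpha > beta > 0")
    total = coeff_a + coeff_b
    v1 = 1.0 / total
    k21 = (coeff_a * beta + coeff_b * alpha) / total
    k10 = alpha * beta / k21
    k12 = alpha + beta - k10 - k21
    if k12 <= 0:
        raise ModelDomainError("macro constants imply non-positive k12")
    return TwoCptParams(volume_v1_l=v1, k10=k10, k12=k12, k21=k21)


def derived_params(
    params: OneCptParams | TwoCptParams, dose: InfusionEvent
) -> DerivedPK:
    """Clearance, Vss, terminal half-life, single-dose AUC and Cavg,ss.

    Under linear kinetics ``AUC(0,inf) = dose/CL`` for a single dose, which
    equals the steady-state AUC over one dosing interval, so
    ``Cavg,ss = AUC / tau``.
    """
    if isinstance(params, OneCptParams):
        cl = params.clearance_l_min
        vss = params.volume_l
        t_half = LN2 / params.k_elim
    else:
        cl = params.clearance_l_min
        vss = params.volume_v1_l * (1.0 + params.k12 / params.k21)
        t_half = LN2 / macro_from_micro(params).beta
    auc = dose.dose_amount_mg / cl
    return DerivedPK(
        clearance_l_min=cl,
        vss_l=vss,
        terminal_half_life_min=t_half,
        auc_0_inf_mg_min_l=auc,
        cavg_ss_mg_l=auc / dose.tau_min,
    )
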