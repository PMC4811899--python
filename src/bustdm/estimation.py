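"""Individual-profile parameter estimation.

The fitting strategy mirrors classical clinical-pharmacology practice:

1. *Curve stripping* (method of residuals): sequential log-linear
   regressions peel the terminal phase and, if the early residuals support
   it, a faster distribution phase — giving starting values for nonlinear
   fitting without any population prior.
2. *Weighted nonlinear least squares* solved by Levenberg-Marquardt, with
   positivity enforced by fitting log-parameters and a 1/yhat^2 weighting
   applied via a small number of outer iteratively-reweighted passes.
3. *Nested model selection*: a cascade of rules decides between the one-
   and two-compartment models (extra-sum-of-squares F test by default) and
   flags profiles that should fall back to non-compartmental analysis.

Every threshold in the cascade lives in :class:`~bustdm.config.AnalysisConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray
from scipy import optimize, stats

from .config import AnalysisConfig, DEFAULT_CONFIG
from .io_profiles import TdmProfile, validate_profile
from .pkmodels import (
    DegenerateModelError,
    InfusionEvent,
    MacroConstants,
    OneCptParams,
    TwoCptParams,
    conc_onecpt,
    conc_twocpt,
    macro_from_micro,
    micro_from_macro,
)

__all__ = [
    "StrippingEstimate",
    "FitResult",
    "ModelChoice",
    "StrippingError",
    "AnalysisImpossibleError",
    "strip_estimates",
    "fit_model",
    "select_model",
    "override_route",
]


class StrippingError(ValueError):
    """Curve stripping cannot proceed (non-positive or too few points)."""


class AnalysisImpossibleError(ValueError):
    """Profile cannot support any analysis route, compartmental or NCA."""


@dataclass(frozen=True)
class StrippingEstimate:
    """Initial estimates from the method of residuals.

    ``candidate_1cpt`` holds (B, lambda) of the terminal monoexponential
    (times measured from end of infusion); ``candidate_2cpt`` additionally
    holds (A, alpha) from the residual regression when the early points
    support a second, faster phase.
    """

    terminal_b_mg_l: float
    terminal_lambda: float
    n_terminal_points: int
    terminal_r2: float
    residual_a_mg_l: float | None = None
    residual_alpha: float | None = None

    @property
    def has_two_exp_candidate(self) -> bool:
        return self.residual_a_mg_l is not None


@dataclass(frozen=True)
class FitResult:
    """A converged (or capped) weighted least-squares compartmental fit."""

    model_order: int
    params: OneCptParams | TwoCptParams
    macro: MacroConstants | tuple[float, float]  # order 1: (B at end of infusion, lambda)
    predictions_mg_l: tuple[float, ...]
    weights: tuple[float, ...]
    weighted_ss: float
    param_cv_pct: tuple[float, ...]  # macro-scale: coefficients then exponents
    micro_cv_pct: tuple[float, ...]
    converged: bool
    n_iterations: int

    @property
    def clearance_l_min(self) -> float:
        return self.params.clearance_l_min


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of the nested selection logic."""

    route: str  # compartmental_1 | compartmental_2 | nca_fallback
    reason_codes: tuple[str, ...]
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        if self.route == "nca_fallback" and not self.reason_codes:
            raise ValueError("nca_fallback requires at least one reason code")


# --------------------------------------------------------------------------
# curve stripping

def _loglinear(t: NDArray, c: NDArray) -> tuple[float, float, float]:
    """Least-squares line through (t, log c); returns (intercept-exp, rate, r2)."""
    logc = np.log(c)
    slope, intercept = np.polyfit(t, logc, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((logc - pred) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.exp(intercept)), float(-slope), r2


def strip_estimates(profile: TdmProfile) -> StrippingEstimate:
    """Initial parameter estimates by the method of residuals.

    The terminal window is the last 3 post-infusion points, or the last half
    when more than 6 are available (ties on even counts resolve to the larger
    window).  A log-linear regression on the window gives (B, lambda); the
    earlier points' residuals against the terminal line give (A, alpha) when
    at least two residuals are strictly positive.
    """
    post = profile.post_infusion_samples()
    if len(post) < 3:
        raise StrippingError(
            f"need >=3 post-infusion samples for stripping, found {len(post)}"
        )
    t_inf = profile.dose.infusion_duration_min
    t = np.array([s.time_min - t_inf for s in post])
    c = np.array([s.conc_mg_l for s in post])

    n = len(post)
    # last half (floor) keeps the fast phase out of the terminal window;
    # at n <= 6 the window is the minimal 3 points
    n_term = 3 if n <= 6 else n // 2
    t_term, c_term = t[-n_term:], c[-n_term:]
    if np.any(c_term <= 0):
        raise StrippingError("non-positive concentration in terminal stripping window")
    if len(np.unique(t_term)) < 2:
        raise StrippingError("terminal stripping window has no time spread")

    b, lam, r2 = _loglinear(t_term, c_term)
    if lam <= 0:
        raise StrippingError("terminal phase does not decline (lambda <= 0)")

    est = StrippingEstimate(
        terminal_b_mg_l=b, terminal_lambda=lam, n_terminal_points=n_term, terminal_r2=r2
    )

    # residual (distribution-phase) strip on the earlier points
    t_early, c_early = t[:-n_term], c[:-n_term]
    resid = c_early - b * np.exp(-lam * t_early)
    pos = resid > 0
    if np.count_nonzero(pos) >= 2:
        a, alpha, _ = _loglinear(t_early[pos], resid[pos])
        if alpha > lam:
            est = replace(est, residual_a_mg_l=a, residual_alpha=alpha)
    return est


# --------------------------------------------------------------------------
# initial micro-constant values from stripped exponentials

def _init_onecpt(est: StrippingEstimate, dose: InfusionEvent) -> OneCptParams:
    """Map the stripped terminal line to (CL, V).

    B back-extrapolates to the concentration at end of infusion, which for
    the one-compartment model is (R0/CL)(1 - exp(-k*T_inf)).
    """
    k = est.terminal_lambda
    r0 = dose.infusion_rate_mg_min
    cl = r0 * -math.expm1(-k * dose.infusion_duration_min) / est.terminal_b_mg_l
    return OneCptParams(clearance_l_min=cl, volume_l=cl / k)


def _init_twocpt(est: StrippingEstimate, dose: InfusionEvent) -> TwoCptParams:
    """Map stripped post-infusion exponentials to micro constants.

    The stripped coefficients describe the *post-infusion* curve measured
    from end of infusion; each is rescaled by lambda*T_inf/(1-exp(-lambda*
    T_inf)) to the equivalent unit-bolus coefficient before the standard
    macro-to-micro inversion.
    """
    if not est.has_two_exp_candidate:
        raise StrippingError("no two-exponential stripping candidate")
    t_inf = dose.infusion_duration_min
    d = dose.dose_amount_mg

    def to_bolus(coeff: float, lam: float) -> float:
        return coeff * lam * t_inf / -math.expm1(-lam * t_inf) / d

    a_b = to_bolus(est.residual_a_mg_l, est.residual_alpha)  # type: ignore[arg-type]
    b_b = to_bolus(est.terminal_b_mg_l, est.terminal_lambda)
    return micro_from_macro(a_b, b_b, est.residual_alpha, est.terminal_lambda)  # type: ignore[arg-type]


# --------------------------------------------------------------------------
# weighted Levenberg-Marquardt fitting

def _predict(theta_log: NDArray, order: int, dose: InfusionEvent, t: NDArray) -> NDArray:
    with np.errstate(over="ignore", invalid="ignore"):
        p = np.exp(theta_log)
        if order == 1:
            return conc_onecpt(t, OneCptParams(p[0], p[1]), dose)
        return conc_twocpt(t, TwoCptParams(p[0], p[1], p[2], p[3]), dose)


def _weights_from(values: NDArray, scheme: str, floor: float) -> NDArray:
    clamped = np.maximum(values, floor)
    if scheme in ("1/yhat2", "1/y2"):
        return 1.0 / clamped**2
    if scheme == "1/y":
        return 1.0 / clamped
    return np.ones_like(values)


def _macro_vector(theta_log: NDArray, order: int, dose: InfusionEvent) -> NDArray:
    """Coefficient/exponent vector on which CVs are reported.

    Order 1: (B at end of infusion, lambda).  Order 2: (A, B, alpha, beta)
    of the unit-bolus disposition function.
    """
    p = np.exp(theta_log)
    if order == 1:
        params = OneCptParams(p[0], p[1])
        b = float(conc_onecpt(dose.infusion_duration_min, params, dose))
        return np.array([b, params.k_elim])
    macro = macro_from_micro(TwoCptParams(p[0], p[1], p[2], p[3]))
    return np.array([macro.coeff_a, macro.coeff_b, macro.alpha, macro.beta])


def fit_model(
    profile: TdmProfile,
    order: int,
    init: StrippingEstimate,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> FitResult:
    """Fit a compartmental model by weighted Levenberg-Marquardt.

    Minimizes ``sum_i w_i (C_i - Chat(t_i; theta))^2`` over log-transformed
    parameters (positivity without box constraints).  With the default
    predicted-value weighting the weights are refreshed from the current
    predictions over ``config.irls_passes`` outer passes.  Convergence
    failure is recorded on the result, not raised.

    Parameter CVs are reported on two scales: the micro constants actually
    fitted, and the macro coefficients/exponents (delta method) that feed
    the goodness-of-fit score.  A rank-deficient Jacobian at the optimum
    yields infinite CVs.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    samples = profile.included_samples
    t = np.array([s.time_min for s in samples])
    y = np.array([s.conc_mg_l for s in samples])
    dose = profile.dose

    if order == 1:
        p0 = _init_onecpt(init, dose)
        theta = np.log([p0.clearance_l_min, p0.volume_l])
    else:
        try:
            p0 = _init_twocpt(init, dose)
        except (StrippingError, ValueError):
            # fall back to perturbing a one-compartment start into two phases
            q = _init_onecpt(init, dose)
            p0 = TwoCptParams(
                volume_v1_l=q.volume_l * 0.6,
                k10=q.k_elim * 1.5,
                k12=q.k_elim * 0.5,
                k21=q.k_elim * 0.8,
            )
        theta = np.log([p0.volume_v1_l, p0.k10, p0.k12, p0.k21])

    floor = config.weight_floor_mg_l
    scheme = config.weighting
    if scheme == "1/yhat2":
        w = _weights_from(y, "1/y2", floor)  # first pass: observed values
        passes = max(1, config.irls_passes)
    else:
        w = _weights_from(y, scheme, floor)
        passes = 1

    nfev_total = 0
    res = None
    for outer in range(passes):
        sw = np.sqrt(w)

        def residuals(th: NDArray) -> NDArray:
            return sw * (_predict(th, order, dose, t) - y)

        res = optimize.least_squares(
            residuals,
            theta,
            method="lm",
            xtol=config.xtol,
            ftol=config.ftol,
            gtol=1e-12,
            max_nfev=config.max_iterations * (len(theta) + 1),
        )
        theta = res.x
        nfev_total += res.nfev
        if scheme == "1/yhat2" and outer < passes - 1:
            w = _weights_from(_predict(theta, order, dose, t), "1/yhat2", floor)

    assert res is not None
    converged = res.status > 0
    pred = _predict(theta, order, dose, t)
    weighted_ss = float(np.sum(w * (pred - y) ** 2))

    micro_cv, macro_cv = _parameter_cvs(res.jac, theta, order, dose, weighted_ss, len(y))

    p = np.exp(theta)
    if order == 1:
        params: OneCptParams | TwoCptParams = OneCptParams(p[0], p[1])
        mv = _macro_vector(theta, 1, dose)
        macro: MacroConstants | tuple[float, float] = (float(mv[0]), float(mv[1]))
    else:
        params = TwoCptParams(p[0], p[1], p[2], p[3])
        macro = macro_from_micro(params)

    return FitResult(
        model_order=order,
        params=params,
        macro=macro,
        predictions_mg_l=tuple(float(v) for v in pred),
        weights=tuple(float(v) for v in w),
        weighted_ss=weighted_ss,
        param_cv_pct=macro_cv,
        micro_cv_pct=micro_cv,
        converged=converged,
        n_iterations=nfev_total,
    )


def _parameter_cvs(
    jac: NDArray,
    theta: NDArray,
    order: int,
    dose: InfusionEvent,
    weighted_ss: float,
    m: int,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """CV% of micro and macro parameters from the LM Jacobian at the optimum.

    The covariance of the log-parameters is ``s^2 (J'J)^-1`` with
    ``s^2 = SS_w/(m - p)``; because the parameters are log-transformed, the
    square root of a diagonal element is directly the parameter's CV
    (fraction).  Macro CVs propagate through the analytic map by a
    first-order (delta-method) numerical Jacobian.
    """
    p = len(theta)
    n_macro = 2 if order == 1 else 4
    inf_cv = tuple([float("inf")] * p), tuple([float("inf")] * n_macro)
    if m <= p:
        return inf_cv
    jtj = jac.T @ jac
    try:
        cov_log = np.linalg.inv(jtj) * (weighted_ss / (m - p))
    except np.linalg.LinAlgError:
        return inf_cv
    if not np.all(np.isfinite(cov_log)) or np.any(np.diag(cov_log) < 0):
        return inf_cv
    if np.linalg.cond(jtj) > 1e12:
        return inf_cv
    micro_cv = tuple(100.0 * math.sqrt(v) for v in np.diag(cov_log))

    # delta method onto the macro coefficient/exponent scale
    try:
        mv0 = _macro_vector(theta, order, dose)
        jm = np.empty((len(mv0), p))
        h = 1e-6
        for j in range(p):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            jm[:, j] = (_macro_vector(tp, order, dose) - _macro_vector(tm, order, dose)) / (2 * h)
        cov_macro = jm @ cov_log @ jm.T
        macro_cv = tuple(
            100.0 * math.sqrt(max(cov_macro[i, i], 0.0)) / abs(mv0[i])
            for i in range(len(mv0))
        )
    except (DegenerateModelError, ZeroDivisionError):
        return micro_cv, tuple([float("inf")] * n_macro)
    return micro_cv, macro_cv


# --------------------------------------------------------------------------
# nested model selection

def _common_weight_ss(fit: FitResult, profile: TdmProfile, config: AnalysisConfig) -> float:
    """Weighted SS under observation-based weights, comparable across models."""
    samples = profile.included_samples
    y = np.array([s.conc_mg_l for s in samples])
    w = _weights_from(y, "1/y2" if config.weighting != "none" else "none",
                      config.weight_floor_mg_l)
    pred = np.array(fit.predictions_mg_l)
    return float(np.sum(w * (pred - y) ** 2))


def _f_test_p(ss1: float, ss2: float, m: int, p1: int = 2, p2: int = 4) -> float:
    """Extra-sum-of-squares F test of the 2-cpt model against the 1-cpt."""
    df_extra = p2 - p1
    df_resid = m - p2
    if df_resid <= 0 or ss2 <= 0:
        return 1.0
    f = max(0.0, (ss1 - ss2) / df_extra) / (ss2 / df_resid)
    return float(stats.f.sf(f, df_extra, df_resid))


def _aicc(ss: float, m: int, p: int) -> float:
    if m - p - 1 <= 0 or ss <= 0:
        return float("inf")
    return m * math.log(ss / m) + 2 * p + 2 * p * (p + 1) / (m - p - 1)


def select_model(
    profile: TdmProfile, config: AnalysisConfig = DEFAULT_CONFIG
) -> ModelChoice:
    """Nested selection between 1-/2-compartment fits with NCA fallback.

    The cascade (all thresholds from ``config``):

    1. Fewer than ``min_points_two_cpt`` post-infusion points: fit the
       one-compartment model only.
    2. Otherwise, if stripping yields a two-exponential candidate, fit both
       orders; accept the two-compartment fit only if it converged, every
       macro-constant CV is below ``max_param_cv_pct``, the exponents are
       separated by at least ``min_alpha_beta_ratio``, and the extra-sum-of-
       squares F test (or AICc) favors it.
    3. Fall back to non-compartmental analysis when no compartmental fit
       converged, the accepted fit carries a parameter CV at or above
       ``fallback_cv_pct``, or the profile showed a non-monotone decline and
       the accepted fit's tachometer band is red.
    """
    issues = validate_profile(profile, config)
    errors = [i for i in issues if i.severity == "error"]
    post = profile.post_infusion_samples()
    if len(post) < 3:
        raise AnalysisImpossibleError(
            f"only {len(post)} usable post-infusion samples; no analysis possible"
        )
    if errors:
        raise AnalysisImpossibleError("; ".join(i.message for i in errors))

    m = len(post)
    reasons: list[str] = []

    try:
        est = strip_estimates(profile)
    except StrippingError as exc:
        return ModelChoice(
            route="nca_fallback", reason_codes=("stripping_failed",), fit=None
        )

    # a fit that cannot be evaluated at all counts as a non-converged fit
    try:
        fit1: FitResult | None = fit_model(profile, 1, est, config)
    except (ValueError, np.linalg.LinAlgError):
        fit1 = None
    accepted = fit1
    route = "compartmental_1"

    if m < config.min_points_two_cpt:
        reasons.append("few_post_infusion_points")
    elif not est.has_two_exp_candidate:
        reasons.append("one_exponential_candidate")
    else:
        try:
            fit2: FitResult | None = fit_model(profile, 2, est, config)
        except (ValueError, np.linalg.LinAlgError):
            fit2 = None
        accept2 = False
        if fit2 is not None and fit1 is not None:
            macro2 = fit2.macro
            assert isinstance(macro2, MacroConstants)
            ratio = macro2.alpha / macro2.beta
            cv_ok = all(cv < config.max_param_cv_pct for cv in fit2.param_cv_pct)
            ss1 = _common_weight_ss(fit1, profile, config)
            ss2 = _common_weight_ss(fit2, profile, config)
            if config.model_criterion == "aicc":
                stat_ok = _aicc(ss2, m, 4) < _aicc(ss1, m, 2)
            else:
                stat_ok = _f_test_p(ss1, ss2, m) < config.f_test_alpha
            accept2 = (
                fit2.converged and cv_ok and ratio >= config.min_alpha_beta_ratio and stat_ok
            )
        if accept2:
            accepted, route = fit2, "compartmental_2"
            reasons.append("two_compartment_accepted")
        else:
            reasons.append("two_compartment_rejected")

    # --- NCA fallback triggers (all satisfied conditions are recorded) ---
    fallback: list[str] = []
    if accepted is None or not accepted.converged:
        fallback.append("no_convergence")
    if accepted is not None and any(
        cv >= config.fallback_cv_pct for cv in accepted.param_cv_pct
    ):
        fallback.append("high_parameter_cv")
    if accepted is not None and any(i.code == "non_monotone_decline" for i in issues):
        from . import gof as _gof  # deferred: gof consumes FitResult

        band = _gof.gof_score(_gof.gof_components(accepted, profile), config).band
        if band == "red":
            fallback.append("non_monotone_red_fit")
    if fallback:
        return ModelChoice(
            route="nca_fallback",
            reason_codes=tuple(reasons) + tuple(fallback),
            fit=accepted,
        )

    assert accepted is not None
    return ModelChoice(route=route, reason_codes=tuple(reasons), fit=accepted)


def override_route(
    choice: ModelChoice,
    user_route: str,
    profile: TdmProfile,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ModelChoice:
    """Apply a clinician override of the automatic route.

    ``user_route`` is ``"nca"`` or ``"compartmental"``.  The reason trail is
    preserved and ``user_override`` appended, so reports show both what the
    software chose and what the user decided.
    """
    reasons = choice.reason_codes + ("user_override",)
    if user_route == "nca":
        return ModelChoice(route="nca_fallback", reason_codes=reasons, fit=choice.fit)
    if user_route == "compartmental":
        if choice.fit is not None:
            route = f"compartmental_{choice.fit.model_order}"
            return ModelChoice(route=route, reason_codes=reasons, fit=choice.fit)
        # no fit attached (e.g. stripping failed): must be computable now
        est = strip_estimates(profile)  # raises if not
        fit1 = fit_model(profile, 1, est, config)
        return ModelChoice(route="compartmental_1", reason_codes=reasons, fit=fit1)
    raise ValueError(f"user_route must be 'nca' or 'compartmental', got {user_route!r}")
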