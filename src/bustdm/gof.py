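"""Goodness-of-fit tachometer: component metrics collapsed to a 0-10 score.

The fit-quality ingredients are the weighted residual magnitude and the
coefficients of variation of the fitted coefficients and exponents.  Each
component metric is log-adjusted against a reference value, clamped to the
0-10 scale, and the components are combined by a weighted mean:

    s_j = clamp(10 - c * log10(max(m_j, eps) / ref_j), 0, 10)

so a component exactly at its reference still scores 10 and each decade
above the reference costs ``c`` points (default 3).  The composite score
maps to a three-color band — green (>= 7) means the model is strong, yellow
(>= 4) signals caution, red flags a problem — so a non-specialist can judge
a fit at a glance.  References, slopes, weights and band cut-points are all
configuration, not constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .estimation import FitResult
from .io_profiles import TdmProfile

_EPS = 1e-12


@dataclass(frozen=True)
class GofComponents:
    """Raw fit-quality metrics before scaling.

    ``weighted_rmse_frac`` is the weighted root-mean-square residual as a
    fraction of the weighted mean observed concentration; the CV lists are
    percent CVs of the macro coefficients and exponents.
    """

    weighted_rmse_frac: float
    cv_coefficients_pct: tuple[float, ...]
    cv_exponents_pct: tuple[float, ...]


@dataclass(frozen=True)
class GofScore:
    component_scores: tuple[float, ...]
    score: float
    band: str  # green | yellow | red


def gof_components(fit: FitResult, profile: TdmProfile) -> GofComponents:
    """Extract the scoreable metrics from a fit.

    The RMSE fraction recomputes ``sqrt(SS_w/m)`` from the fit's stored
    weighted sum of squares and normalizes by the weighted mean observed
    concentration, so perfect predictions give exactly zero.
    """
    y = np.array([s.conc_mg_l for s in profile.included_samples])
    m = len(y)
    if m == 0:
        raise ValueError("profile has no included samples")
    w = np.array(fit.weights)
    wmean = float(np.sum(w * y) / np.sum(w))
    rmse_frac = math.sqrt(fit.weighted_ss / m) / wmean

    cvs = fit.param_cv_pct
    half = len(cvs) // 2
    return GofComponents(
        weighted_rmse_frac=rmse_frac,
        cv_coefficients_pct=tuple(cvs[:half]),
        cv_exponents_pct=tuple(cvs[half:]),
    )


def _component_score(metric: float, ref: float, slope: float) -> float:
    if math.isinf(metric):
        return 0.0
    return min(10.0, max(0.0, 10.0 - slope * math.log10(max(metric, _EPS) / ref)))


def gof_score(
    components: GofComponents, config: AnalysisConfig = DEFAULT_CONFIG
) -> GofScore:
    """Collapse component metrics to the 10-point score and color band."""
    metrics = [(components.weighted_rmse_frac, config.gof_ref_rmse_frac)]
    for cv in components.cv_coefficients_pct:
        metrics.append((cv, config.gof_ref_cv_pct))
    for cv in components.cv_exponents_pct:
        metrics.append((cv, config.gof_ref_cv_pct))

    scores = tuple(_component_score(m, ref, config.gof_slope) for m, ref in metrics)
    weights = config.gof_component_weights
    if weights is None:
        weights = tuple(1.0 for _ in scores)
    if len(weights) != len(scores):
        raise ValueError(
            f"gof_component_weights has {len(weights)} entries for {len(scores)} components"
        )
    score = float(np.average(scores, weights=weights))

    if score >= config.gof_green_min:
        band = "green"
    elif score >= config.gof_yellow_min:
        band = "yellow"
    else:
        band = "red"
    return GofScore(component_scores=scores, score=score, band=band)
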