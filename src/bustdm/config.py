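"""Analysis configuration: every policy threshold in one place.

The fitting, model-selection, goodness-of-fit and dose-simulation modules
take their tunables from a single :class:`AnalysisConfig` so that a site can
recalibrate the pipeline (weighting scheme, nested-model thresholds, GOF
reference values, banding cut-points) without touching code.  Configs load
from YAML or JSON mappings whose keys match the field names exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Molar mass of busulfan (g/mol); used only for micromolar unit conversion.
BUSULFAN_MOLAR_MASS_G_MOL = 246.3

_WEIGHTING_SCHEMES = ("1/yhat2", "1/y2", "1/y", "none")
_MODEL_CRITERIA = ("ftest", "aicc")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable policy for the full TDM analysis pipeline.

    Attributes
    ----------
    weighting:
        Residual weighting scheme for the least-squares objective.
        ``"1/yhat2"`` (default) weights by the reciprocal squared *predicted*
        concentration, iteratively reweighted; ``"1/y2"`` and ``"1/y"`` use
        the observed concentration; ``"none"`` is ordinary least squares.
    weight_floor_mg_l:
        Concentrations below this floor (mg/L) are clamped when forming
        weights so near-zero values cannot dominate the objective.
    irls_passes:
        Outer iteratively-reweighted passes when ``weighting="1/yhat2"``.
    min_points_two_cpt:
        Minimum post-infusion samples before a two-compartment fit is even
        attempted; sparser profiles are fit one-compartment only.
    max_param_cv_pct:
        A two-compartment fit is rejected if any macro-constant CV% exceeds
        this bound.
    min_alpha_beta_ratio:
        Minimum separation of the fast and slow exponents for a
        two-compartment fit to be accepted.
    f_test_alpha:
        Significance level for the extra-sum-of-squares F test that the
        richer model must pass.
    fallback_cv_pct:
        Automatic non-compartmental fallback triggers when the accepted
        compartmental fit carries any parameter CV% at or above this bound.
    model_criterion:
        Nested-model discriminator: ``"ftest"`` (default) or ``"aicc"``.
    """

    # --- least-squares fitting ---
    weighting: str = "1/yhat2"
    weight_floor_mg_l: float = 0.01
    irls_passes: int = 3
    max_iterations: int = 200
    xtol: float = 1e-8
    ftol: float = 1e-10

    # --- nested model selection ---
    min_points_two_cpt: int = 5
    max_param_cv_pct: float = 50.0
    min_alpha_beta_ratio: float = 2.0
    f_test_alpha: float = 0.05
    model_criterion: str = "ftest"

    # --- non-compartmental fallback policy ---
    fallback_cv_pct: float = 100.0
    nca_use_predicted_clast: bool = True
    nca_high_extrapolation_fraction: float = 0.20

    # --- goodness-of-fit tachometer ---
    gof_ref_rmse_frac: float = 0.10
    gof_ref_cv_pct: float = 25.0
    gof_slope: float = 3.0
    gof_component_weights: tuple[float, ...] | None = None  # None = equal
    gof_green_min: float = 7.0
    gof_yellow_min: float = 4.0

    # --- profile validation ---
    non_monotone_rise_fraction: float = 0.20

    # --- dose simulation ---
    dose_rounding_grid_mg: float = 5.0

    # --- unit handling ---
    molar_mass_g_mol: float = BUSULFAN_MOLAR_MASS_G_MOL

    def __post_init__(self) -> None:
        if self.weighting not in _WEIGHTING_SCHEMES:
            raise ValueError(
                f"weighting must be one of {_WEIGHTING_SCHEMES}, got {self.weighting!r}"
            )
        if self.model_criterion not in _MODEL_CRITERIA:
            raise ValueError(
                f"model_criterion must be one of {_MODEL_CRITERIA}, got {self.model_criterion!r}"
            )
        if not (0.0 <= self.gof_yellow_min <= self.gof_green_min <= 10.0):
            raise ValueError("GOF band cut-points must satisfy 0 <= yellow <= green <= 10")
        if self.weight_floor_mg_l <= 0:
            raise ValueError("weight_floor_mg_l must be positive")

    def replace(self, **changes: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["gof_component_weights"] is not None:
            d["gof_component_weights"] = list(d["gof_component_weights"])
        return d

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if kwargs.get("gof_component_weights") is not None:
            kwargs["gof_component_weights"] = tuple(kwargs["gof_component_weights"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML (or JSON, a YAML subset) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            return cls()
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def digest(self) -> str:
        """Deterministic short hash of the effective configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


DEFAULT_CONFIG = AnalysisConfig()
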