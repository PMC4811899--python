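"""Report assembly and the append-only report registry.

A report bundles the analysis route, its fit or NCA result, the tachometer
score and the dose recommendation into a time-stamped, JSON-round-trippable
record plus a human-readable text rendering that mirrors the clinical
workflow (data table, model & fit quality, simulation, recommendation).

The registry is an append-only JSON-lines file keyed by (patient, study):
re-submitting a report for the same study stores it but raises a duplicate
warning flag, so a second report for the same child is never silent.  The
clock is always injected by the caller, never read ambiently, which makes
report generation fully deterministic and testable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from . import __version__
from .config import AnalysisConfig, DEFAULT_CONFIG
from .dosesim import DoseRecommendation, ExposureSummary, TherapeuticTarget
from .estimation import FitResult, ModelChoice
from .gof import GofScore
from .io_profiles import TdmProfile, profile_to_dict
from .nca import NcaResult
from .pkmodels import MacroConstants, OneCptParams, TwoCptParams


class ReportConsistencyError(ValueError):
    """Report inputs come from different profiles/runs."""


@dataclass(frozen=True)
class Report:
    patient_id: str
    study_id: str
    created_at: str  # ISO-8601, injected by the caller
    route: str
    fit: FitResult | None
    nca_result: NcaResult | None
    reason_codes: tuple[str, ...]
    gof: GofScore | None
    recommendation: DoseRecommendation
    comments: str
    software_version: str
    config_digest: str

    def __post_init__(self) -> None:
        if (self.fit is None) == (self.nca_result is None):
            raise ReportConsistencyError(
                "exactly one of fit / nca_result must be present for the chosen route"
            )


def build_report(
    profile: TdmProfile,
    choice: ModelChoice,
    gof_score: GofScore | None,
    recommendation: DoseRecommendation,
    comments: str,
    created_at: str,
    nca_result: NcaResult | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Report:
    """Assemble the final report from one analysis run.

    ``created_at`` is the injected timestamp.  For compartmental routes the
    accepted fit travels with the report; for the NCA route the caller
    passes the :class:`~bustdm.nca.NcaResult`.
    """
    if choice.route.startswith("compartmental"):
        if choice.fit is None:
            raise ReportConsistencyError("compartmental route without a fit")
        fit, nca_res = choice.fit, None
    else:
        if nca_result is None:
            raise ReportConsistencyError("nca_fallback route requires an NcaResult")
        fit, nca_res = None, nca_result

    if abs(recommendation.clearance_l_min - _route_clearance(fit, nca_res)) > 1e-9 * max(
        recommendation.clearance_l_min, 1e-12
    ):
        raise ReportConsistencyError(
            "recommendation clearance does not match the analysis route's clearance"
        )

    return Report(
        patient_id=profile.patient_id,
        study_id=profile.study_id,
        created_at=created_at,
        route=choice.route,
        fit=fit,
        nca_result=nca_res,
        reason_codes=choice.reason_codes,
        gof=gof_score,
        recommendation=recommendation,
        comments=comments,
        software_version=__version__,
        config_digest=config.digest(),
    )


def _route_clearance(fit: FitResult | None, nca_res: NcaResult | None) -> float:
    return fit.clearance_l_min if fit is not None else nca_res.clearance_l_min  # type: ignore[union-attr]


# --------------------------------------------------------------------------
# JSON serialization

def _encode(obj: Any) -> Any:
    if isinstance(obj, (OneCptParams, TwoCptParams, MacroConstants)):
        return {"__type__": type(obj).__name__, **dataclasses.asdict(obj)}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _encode(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, float) and math.isinf(obj):
        return "Infinity"
    return obj


def report_to_json(report: Report) -> str:
    """Serialize to a stable, sorted-key JSON document."""
    doc = {
        "patient_id": report.patient_id,
        "study_id": report.study_id,
        "created_at": report.created_at,
        "route": report.route,
        "reason_codes": list(report.reason_codes),
        "fit": _fit_to_dict(report.fit) if report.fit else None,
        "nca_result": _encode(report.nca_result) if report.nca_result else None,
        "gof": _encode(report.gof) if report.gof else None,
        "recommendation": _encode(report.recommendation),
        "comments": report.comments,
        "software_version": report.software_version,
        "config_digest": report.config_digest,
    }
    return json.dumps(doc, sort_keys=True, indent=2)


def _fit_to_dict(fit: FitResult) -> dict[str, Any]:
    d = _encode(fit)
    d["params"] = {"__type__": type(fit.params).__name__, **dataclasses.asdict(fit.params)}
    if isinstance(fit.macro, MacroConstants):
        d["macro"] = {"__type__": "MacroConstants", **dataclasses.asdict(fit.macro)}
    return d


def _decode_inf(x: Any) -> Any:
    return float("inf") if x == "Infinity" else x


def report_from_json(doc: str) -> Report:
    """Reconstruct a :class:`Report` from its JSON document (lossless)."""
    d = json.loads(doc)
    fit = None
    if d["fit"] is not None:
        f = d["fit"]
        pd_ = dict(f["params"])
        ptype = pd_.pop("__type__")
        params = OneCptParams(**pd_) if ptype == "OneCptParams" else TwoCptParams(**pd_)
        macro_raw = f["macro"]
        if isinstance(macro_raw, dict):
            macro_raw = dict(macro_raw)
            macro_raw.pop("__type__", None)
            macro: MacroConstants | tuple[float, float] = MacroConstants(**macro_raw)
        else:
            macro = tuple(macro_raw)  # type: ignore[assignment]
        fit = FitResult(
            model_order=f["model_order"],
            params=params,
            macro=macro,
            predictions_mg_l=tuple(f["predictions_mg_l"]),
            weights=tuple(f["weights"]),
            weighted_ss=f["weighted_ss"],
            param_cv_pct=tuple(_decode_inf(v) for v in f["param_cv_pct"]),
            micro_cv_pct=tuple(_decode_inf(v) for v in f["micro_cv_pct"]),
            converged=f["converged"],
            n_iterations=f["n_iterations"],
        )
    nca_res = None
    if d["nca_result"] is not None:
        n = d["nca_result"]
        nca_res = NcaResult(
            lambda_z=n["lambda_z"],
            lambda_z_r2_adj=n["lambda_z_r2_adj"],
            n_terminal=n["n_terminal"],
            auc_last_mg_min_l=n["auc_last_mg_min_l"],
            auc_inf_mg_min_l=n["auc_inf_mg_min_l"],
            extrap_fraction=n["extrap_fraction"],
            clearance_l_min=n["clearance_l_min"],
            flags=tuple(n["flags"]),
        )
    gof_score = None
    if d["gof"] is not None:
        g = d["gof"]
        gof_score = GofScore(
            component_scores=tuple(g["component_scores"]), score=g["score"], band=g["band"]
        )
    r = d["recommendation"]
    target = TherapeuticTarget(**r["target"])

    def _exp(e: dict[str, Any]) -> ExposureSummary:
        return ExposureSummary(**e)

    rec = DoseRecommendation(
        current_dose_mg=r["current_dose_mg"],
        recommended_dose_mg=r["recommended_dose_mg"],
        change_at_dose=r["change_at_dose"],
        total_doses=r["total_doses"],
        clearance_l_min=r["clearance_l_min"],
        target=target,
        predicted=_exp(r["predicted"]),
        rounded_variants=tuple((v[0], _exp(v[1])) for v in r["rounded_variants"]),
    )
    return Report(
        patient_id=d["patient_id"],
        study_id=d["study_id"],
        created_at=d["created_at"],
        route=d["route"],
        fit=fit,
        nca_result=nca_res,
        reason_codes=tuple(d["reason_codes"]),
        gof=gof_score,
        recommendation=rec,
        comments=d["comments"],
        software_version=d["software_version"],
        config_digest=d["config_digest"],
    )


# --------------------------------------------------------------------------
# text rendering

def render_text(report: Report, profile: TdmProfile) -> str:
    """Human-readable report following the clinical review flow."""
    lines = [
        "=" * 64,
        "BUSULFAN TDM REPORT",
        f"Patient: {report.patient_id}    Study: {report.study_id}",
        f"Created: {report.created_at}    Software: bustdm {report.software_version}",
        f"Config digest: {report.config_digest}",
        "=" * 64,
        "",
        "-- Study data " + "-" * 50,
        f"Dose: {profile.dose.dose_amount_mg:g} mg over "
        f"{profile.dose.infusion_duration_min:g} min, q{profile.dose.tau_min:g} min, "
        f"dose {profile.dose.dose_number} of {profile.dose.total_planned_doses}",
        f"Dosing weight: {profile.dosing_weight_kg:g} kg",
        f"{'t (min)':>10} {'conc (mg/L)':>14} {'excluded':>10}  note",
    ]
    for s in profile.samples:
        lines.append(
            f"{s.time_min:>10g} {s.conc_mg_l:>14.4g} {str(s.excluded):>10}  {s.note}"
        )

    lines += ["", "-- Model & fit quality " + "-" * 41, f"Route: {report.route}"]
    if report.reason_codes:
        lines.append(f"Reasons: {', '.join(report.reason_codes)}")
    if report.fit is not None:
        f = report.fit
        lines.append(f"Model: {f.model_order}-compartment, converged={f.converged}")
        lines.append(f"Clearance: {f.clearance_l_min:.4g} L/min")
        lines.append(f"Weighted SS: {f.weighted_ss:.4g}")
        lines.append(
            "Parameter CV% (coefficients/exponents): "
            + ", ".join(f"{cv:.1f}" for cv in f.param_cv_pct)
        )
    if report.nca_result is not None:
        n = report.nca_result
        lines.append(f"NCA: lambda_z={n.lambda_z:.5g}/min (r2adj={n.lambda_z_r2_adj:.3f})")
        lines.append(
            f"AUC(0,last)={n.auc_last_mg_min_l:.4g}, AUC(0,inf)={n.auc_inf_mg_min_l:.4g} "
            f"mg*min/L ({100 * n.extrap_fraction:.1f}% extrapolated)"
        )
        lines.append(f"Clearance: {n.clearance_l_min:.4g} L/min")
        if n.flags:
            lines.append(f"Flags: {', '.join(n.flags)}")
    if report.gof is not None:
        lines.append(
            f"Goodness of fit: {report.gof.score:.1f}/10 ({report.gof.band.upper()})"
        )

    rec = report.recommendation
    lines += [
        "",
        "-- Simulation & recommendation " + "-" * 33,
        f"Target: {rec.target.kind} = {rec.target.value:g}"
        + (f" (entered as {rec.target.units_in})" if rec.target.units_in else ""),
        f"Clearance used: {rec.clearance_l_min:.4g} L/min",
        f"Current dose: {rec.current_dose_mg:g} mg; "
        f"recommended: {rec.recommended_dose_mg:.2f} mg "
        f"({rec.recommended_dose_mg / profile.dosing_weight_kg:.3f} mg/kg) "
        f"from dose {rec.change_at_dose} of {rec.total_doses}",
        f"Predicted per-dose AUC: {rec.predicted.auc_per_dose_mg_min_l:.1f} mg*min/L; "
        f"Cavg,ss: {rec.predicted.cavg_ss_mg_l:.3f} mg/L",
    ]
    if rec.predicted.cumulative_auc_mg_min_l is not None:
        lines.append(
            f"Predicted cumulative course AUC: "
            f"{rec.predicted.cumulative_auc_mg_min_l:.1f} mg*min/L"
        )
    for dose_mg, exp in rec.rounded_variants:
        lines.append(
            f"  rounded {dose_mg:g} mg -> AUC {exp.auc_per_dose_mg_min_l:.1f}, "
            f"Cavg,ss {exp.cavg_ss_mg_l:.3f}"
            + (
                f", cumulative {exp.cumulative_auc_mg_min_l:.1f}"
                if exp.cumulative_auc_mg_min_l is not None
                else ""
            )
        )
    if report.comments:
        lines += ["", "-- Comments " + "-" * 52, report.comments]
    lines.append("=" * 64)
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# registry

@dataclass
class ReportRegistry:
    """Append-only JSON-lines store of submitted reports."""

    path: Path

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)

    def _entries(self) -> list[dict[str, Any]]:
        if not self.path.exists():
            return []
        entries = []
        with open(self.path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    entries.append(json.loads(line))
        return entries

    def count(self) -> int:
        return len(self._entries())

    def has_report(self, patient_id: str, study_id: str | None = None) -> bool:
        for e in self._entries():
            if e["patient_id"] == patient_id and (
                study_id is None or e["study_id"] == study_id
            ):
                return True
        return False


def register_report(
    registry: ReportRegistry,
    report: Report,
    strict_patient_only: bool = False,
) -> dict[str, bool]:
    """Store a report; warn (never block) on duplicates.

    Duplicate detection keys on (patient, study) so legitimate repeat TDM
    studies for the same child do not warn; ``strict_patient_only=True``
    switches to warning on any prior report for the child.
    """
    duplicate = registry.has_report(
        report.patient_id, None if strict_patient_only else report.study_id
    )
    entry = {
        "patient_id": report.patient_id,
        "study_id": report.study_id,
        "created_at": report.created_at,
        "route": report.route,
        "recommended_dose_mg": report.recommendation.recommended_dose_mg,
        "report_json": report_to_json(report),
    }
    registry.path.parent.mkdir(parents=True, exist_ok=True)
    with open(registry.path, "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return {"stored": True, "duplicate_warning": duplicate}
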