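"""Profile data model and I/O for busulfan TDM studies.

A TDM study is one monitored infusion dose plus a handful of timed plasma
concentrations.  This module defines the immutable in-memory containers
(:class:`InfusionEvent`, :class:`ConcSample`, :class:`TdmProfile`), readers
and writers for the CSV and JSON exchange schemas, validation against the
analysis preconditions, and reversible point exclusion (the library analog
of a clinician flagging a contaminated sample).

Conventions: all times are minutes relative to the infusion start of the
studied dose; all concentrations are mg/L; dose amounts are mg.  Unit
conversion happens at parse time only.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, IO, Iterable, Literal, Sequence

import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG


class ProfileError(ValueError):
    """Raised for unparseable or invariant-violating profile input."""


class UnitError(ProfileError):
    """Raised for an unrecognized concentration unit string."""


@dataclass(frozen=True)
class InfusionEvent:
    """One zero-order IV infusion dose within a dosing course.

    ``time_origin`` is an opaque label for the real-world infusion start
    (timestamp string or 0); sample times are measured from it.
    """

    dose_amount_mg: float
    infusion_duration_min: float
    tau_min: float
    dose_number: int = 1
    total_planned_doses: int = 1
    time_origin: str = "0"

    def __post_init__(self) -> None:
        if not self.dose_amount_mg > 0:
            raise ProfileError(f"dose_amount_mg must be > 0, got {self.dose_amount_mg}")
        if not 0 < self.infusion_duration_min < self.tau_min:
            raise ProfileError(
                "infusion_duration_min must lie strictly between 0 and tau_min "
                f"(got T_inf={self.infusion_duration_min}, tau={self.tau_min})"
            )
        if not 1 <= self.dose_number <= self.total_planned_doses:
            raise ProfileError(
                f"dose_number {self.dose_number} outside 1..{self.total_planned_doses}"
            )

    @property
    def infusion_rate_mg_min(self) -> float:
        """Zero-order input rate R0 = dose / T_inf (mg/min)."""
        return self.dose_amount_mg / self.infusion_duration_min


@dataclass(frozen=True)
class ConcSample:
    """One timed plasma concentration; exclusion is a reversible flag."""

    time_min: float
    conc_mg_l: float
    excluded: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ProfileError(f"sample time must be >= 0 min, got {self.time_min}")
        if self.conc_mg_l < 0:
            raise ProfileError(f"concentration must be >= 0 mg/L, got {self.conc_mg_l}")


@dataclass(frozen=True)
class TdmProfile:
    """One TDM study: dose event, samples (time-sorted), patient metadata."""

    patient_id: str
    dosing_weight_kg: float
    dose: InfusionEvent
    samples: tuple[ConcSample, ...]
    assay_lloq_mg_l: float | None = None

    def __post_init__(self) -> None:
        if self.dosing_weight_kg <= 0:
            raise ProfileError(f"dosing_weight_kg must be > 0, got {self.dosing_weight_kg}")
        times = [s.time_min for s in self.samples]
        if times != sorted(times):
            object.__setattr__(
                self, "samples", tuple(sorted(self.samples, key=lambda s: s.time_min))
            )
        if not any(not s.excluded for s in self.samples):
            raise ProfileError("profile needs at least one non-excluded sample")

    @property
    def included_samples(self) -> tuple[ConcSample, ...]:
        return tuple(s for s in self.samples if not s.excluded)

    def post_infusion_samples(self) -> tuple[ConcSample, ...]:
        """Non-excluded samples drawn at or after end of infusion."""
        t_inf = self.dose.infusion_duration_min
        return tuple(s for s in self.included_samples if s.time_min >= t_inf)

    @property
    def study_id(self) -> str:
        """Identity of this TDM study within the patient's course."""
        return f"dose{self.dose.dose_number}@{self.dose.time_origin}"


@dataclass(frozen=True)
class ValidationIssue:
    severity: Literal["error", "warning"]
    code: str
    message: str
    sample_index: int | None = None


# --------------------------------------------------------------------------
# unit handling

_CONC_FACTORS = {
    "mg/l": 1.0,
    "ug/ml": 1.0,
    "µg/ml": 1.0,
    "mcg/ml": 1.0,
    "ng/ml": 1e-3,
    "ug/l": 1e-3,
}


def conc_to_mg_l(value: float, unit: str, molar_mass_g_mol: float) -> float:
    """Convert a concentration in ``unit`` to mg/L.

    Mass units convert by fixed factors; molar units (µmol/L, nmol/L) use the
    configured molar mass.  Conversion is exact and, for the canonical unit,
    the identity (idempotent normalization).
    """
    key = unit.strip().lower().replace("μ", "µ")
    if key in _CONC_FACTORS:
        return value * _CONC_FACTORS[key]
    if key in ("umol/l", "µmol/l", "um", "µm"):
        return value * molar_mass_g_mol * 1e-3
    if key in ("nmol/l", "nm"):
        return value * molar_mass_g_mol * 1e-6
    raise UnitError(f"unknown concentration unit {unit!r}")


# --------------------------------------------------------------------------
# CSV / JSON schemas

CSV_COLUMNS = [
    "patient_id",
    "dosing_weight_kg",
    "dose_mg",
    "infusion_duration_min",
    "tau_min",
    "dose_number",
    "total_doses",
    "sample_time_min",
    "conc",
    "conc_unit",
    "excluded",
    "note",
]

_REQUIRED_CSV = [c for c in CSV_COLUMNS if c not in ("conc_unit", "excluded", "note")]


def _parse_bool(x: Any) -> bool:
    if isinstance(x, bool):
        return x
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return False
    return str(x).strip().lower() in ("true", "1", "yes", "y", "t")


def read_profile(
    source: str | Path | IO[str],
    format: Literal["csv", "json"] = "csv",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> TdmProfile:
    """Read a single TDM study from a CSV or JSON file (or open stream).

    CSV carries one row per sample with the dose fields repeated; JSON
    mirrors the :class:`TdmProfile` field names.  Concentrations are
    normalized to mg/L using ``conc_unit`` (default mg/L) at parse time.
    """
    if format == "csv":
        return _read_csv(source, config)
    if format == "json":
        return _read_json(source, config)
    raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def _read_csv(source: str | Path | IO[str], config: AnalysisConfig) -> TdmProfile:
    df = pd.read_csv(source, dtype={"patient_id": str, "note": str})
    missing = [c for c in _REQUIRED_CSV if c not in df.columns]
    if missing:
        raise ProfileError(f"CSV missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ProfileError("CSV contains no sample rows")

    head = df.iloc[0]
    for col in ("dosing_weight_kg", "dose_mg", "infusion_duration_min", "tau_min",
                "dose_number", "total_doses"):
        if df[col].nunique() != 1:
            raise ProfileError(f"dose-level column {col!r} must be constant across rows")

    dose = InfusionEvent(
        dose_amount_mg=float(head["dose_mg"]),
        infusion_duration_min=float(head["infusion_duration_min"]),
        tau_min=float(head["tau_min"]),
        dose_number=int(head["dose_number"]),
        total_planned_doses=int(head["total_doses"]),
        time_origin=str(head["time_origin"]) if "time_origin" in df.columns else "0",
    )

    samples = []
    for _, row in df.iterrows():
        unit = row.get("conc_unit", "mg/L")
        if unit is None or (isinstance(unit, float) and math.isnan(unit)):
            unit = "mg/L"
        note = row.get("note", "")
        if note is None or (isinstance(note, float) and math.isnan(note)):
            note = ""
        samples.append(
            ConcSample(
                time_min=float(row["sample_time_min"]),
                conc_mg_l=conc_to_mg_l(float(row["conc"]), str(unit), config.molar_mass_g_mol),
                excluded=_parse_bool(row.get("excluded", False)),
                note=str(note),
            )
        )

    lloq = None
    if "assay_lloq_mg_l" in df.columns and not math.isnan(float(head["assay_lloq_mg_l"])):
        lloq = float(head["assay_lloq_mg_l"])

    return TdmProfile(
        patient_id=str(head["patient_id"]),
        dosing_weight_kg=float(head["dosing_weight_kg"]),
        dose=dose,
        samples=tuple(samples),
        assay_lloq_mg_l=lloq,
    )


def _read_json(source: str | Path | IO[str], config: AnalysisConfig) -> TdmProfile:
    if hasattr(source, "read"):
        data = json.load(source)  # type: ignore[arg-type]
    else:
        with open(source) as fh:
            data = json.load(fh)
    try:
        dose_d = data["dose"]
        dose = InfusionEvent(
            dose_amount_mg=float(dose_d["dose_amount_mg"]),
            infusion_duration_min=float(dose_d["infusion_duration_min"]),
            tau_min=float(dose_d["tau_min"]),
            dose_number=int(dose_d.get("dose_number", 1)),
            total_planned_doses=int(dose_d.get("total_planned_doses", 1)),
            time_origin=str(dose_d.get("time_origin", "0")),
        )
        samples = tuple(
            ConcSample(
                time_min=float(s["time_min"]),
                conc_mg_l=conc_to_mg_l(
                    float(s["conc"]), s.get("conc_unit", "mg/L"), config.molar_mass_g_mol
                ),
                excluded=bool(s.get("excluded", False)),
                note=str(s.get("note", "")),
            )
            for s in data["samples"]
        )
        lloq = data.get("assay_lloq_mg_l")
        return TdmProfile(
            patient_id=str(data["patient_id"]),
            dosing_weight_kg=float(data["dosing_weight_kg"]),
            dose=dose,
            samples=samples,
            assay_lloq_mg_l=None if lloq is None else float(lloq),
        )
    except KeyError as exc:
        raise ProfileError(f"JSON profile missing required field: {exc}") from exc


def write_profile(
    profile: TdmProfile,
    dest: str | Path | IO[str],
    format: Literal["csv", "json"] = "csv",
) -> None:
    """Write a profile in the exchange schema; round-trips losslessly."""
    if format == "csv":
        rows = [
            {
                "patient_id": profile.patient_id,
                "dosing_weight_kg": profile.dosing_weight_kg,
                "dose_mg": profile.dose.dose_amount_mg,
                "infusion_duration_min": profile.dose.infusion_duration_min,
                "tau_min": profile.dose.tau_min,
                "dose_number": profile.dose.dose_number,
                "total_doses": profile.dose.total_planned_doses,
                "time_origin": profile.dose.time_origin,
                "sample_time_min": s.time_min,
                "conc": s.conc_mg_l,
                "conc_unit": "mg/L",
                "excluded": s.excluded,
                "note": s.note,
                "assay_lloq_mg_l": profile.assay_lloq_mg_l,
            }
            for s in profile.samples
        ]
        pd.DataFrame(rows).to_csv(dest, index=False)
    elif format == "json":
        data = profile_to_dict(profile)
        if hasattr(dest, "write"):
            json.dump(data, dest, indent=2)  # type: ignore[arg-type]
        else:
            with open(dest, "w") as fh:
                json.dump(data, fh, indent=2)
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def profile_to_dict(profile: TdmProfile) -> dict[str, Any]:
    return {
        "patient_id": profile.patient_id,
        "dosing_weight_kg": profile.dosing_weight_kg,
        "dose": {
            "dose_amount_mg": profile.dose.dose_amount_mg,
            "infusion_duration_min": profile.dose.infusion_duration_min,
            "tau_min": profile.dose.tau_min,
            "dose_number": profile.dose.dose_number,
            "total_planned_doses": profile.dose.total_planned_doses,
            "time_origin": profile.dose.time_origin,
        },
        "samples": [
            {
                "time_min": s.time_min,
                "conc": s.conc_mg_l,
                "conc_unit": "mg/L",
                "excluded": s.excluded,
                "note": s.note,
            }
            for s in profile.samples
        ],
        "assay_lloq_mg_l": profile.assay_lloq_mg_l,
    }


# --------------------------------------------------------------------------
# validation and exclusion management

def validate_profile(
    profile: TdmProfile, config: AnalysisConfig = DEFAULT_CONFIG
) -> list[ValidationIssue]:
    """Check a profile against the analysis preconditions.

    Returns an empty list when the profile is fit-ready.  ``error`` issues
    block any compartmental or non-compartmental analysis; ``warning``
    issues are advisory (the clinician may still exclude or override).
    """
    issues: list[ValidationIssue] = []
    post = profile.post_infusion_samples()

    if len(post) < 3:
        issues.append(
            ValidationIssue(
                "error",
                "insufficient_post_infusion_points",
                f"need >=3 non-excluded post-infusion samples, found {len(post)}",
            )
        )

    # non-monotone decline: consecutive post-infusion rise beyond threshold
    rise = 1.0 + config.non_monotone_rise_fraction
    for prev, curr in zip(post, post[1:]):
        if prev.conc_mg_l > 0 and curr.conc_mg_l > prev.conc_mg_l * rise:
            issues.append(
                ValidationIssue(
                    "warning",
                    "non_monotone_decline",
                    f"post-infusion concentration rises from {prev.conc_mg_l:g} to "
                    f"{curr.conc_mg_l:g} mg/L ({100 * (curr.conc_mg_l / prev.conc_mg_l - 1):.0f}% "
                    f"> {100 * config.non_monotone_rise_fraction:.0f}% threshold)",
                )
            )
            break

    if profile.assay_lloq_mg_l is not None:
        for i, s in enumerate(profile.samples):
            if not s.excluded and s.conc_mg_l < profile.assay_lloq_mg_l:
                issues.append(
                    ValidationIssue(
                        "warning",
                        "below_lloq",
                        f"sample at {s.time_min:g} min ({s.conc_mg_l:g} mg/L) is below "
                        f"the assay LLOQ {profile.assay_lloq_mg_l:g} mg/L",
                        sample_index=i,
                    )
                )

    return issues


def set_exclusion(
    profile: TdmProfile, sample_index: int, excluded: bool, note: str = ""
) -> TdmProfile:
    """Return a copy of ``profile`` with one sample's exclusion flag updated.

    Exclusion is reversible: the sample's time and concentration are never
    altered, only the flag (and optionally the note).
    """
    if not 0 <= sample_index < len(profile.samples):
        raise IndexError(
            f"sample_index {sample_index} out of range 0..{len(profile.samples) - 1}"
        )
    samples = list(profile.samples)
    old = samples[sample_index]
    samples[sample_index] = replace(old, excluded=excluded, note=note or old.note)
    return replace(profile, samples=tuple(samples))
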