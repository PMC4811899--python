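"""Report assembly, JSON round-trip, registry duplicate warnings, CLI."""

import json

import pytest
from click.testing import CliRunner

from bustdm.cli import main as cli_main
from bustdm.config import AnalysisConfig, DEFAULT_CONFIG
from bustdm.dosesim import Regimen, TherapeuticTarget, recommend_dose
from bustdm.estimation import select_model
from bustdm.gof import gof_components, gof_score
from bustdm.io_profiles import write_profile
from bustdm.nca import nca_analyze
from bustdm.reporting import (
    Report,
    ReportConsistencyError,
    ReportRegistry,
    build_report,
    register_report,
    render_text,
    report_from_json,
    report_to_json,
)

CLOCK = "2024-03-01T08:30:00+00:00"


@pytest.fixture
def full_run(onecpt_profile):
    prof, _ = onecpt_profile
    choice = select_model(prof)
    score = gof_score(gof_components(choice.fit, prof))
    regimen = Regimen(
        current_dose_mg=prof.dose.dose_amount_mg,
        tau_min=prof.dose.tau_min,
        change_at_dose=prof.dose.dose_number + 1,
        total_doses=prof.dose.total_planned_doses,
    )
    rec = recommend_dose(
        choice.fit.clearance_l_min, TherapeuticTarget("auc_per_dose", 300.0), regimen
    )
    return prof, choice, score, rec


class TestBuildReport:
    def test_compartmental_report_has_fit_not_nca(self, full_run):
        prof, choice, score, rec = full_run
        rpt = build_report(prof, choice, score, rec, "looks good", CLOCK)
        assert rpt.fit is not None
        assert rpt.nca_result is None
        assert rpt.created_at == CLOCK
        assert rpt.config_digest == DEFAULT_CONFIG.digest()

    def test_nca_report_requires_nca_result(self, full_run):
        prof, choice, score, rec = full_run
        from bustdm.estimation import ModelChoice, override_route

        nca_choice = override_route(choice, "nca", prof)
        with pytest.raises(ReportConsistencyError):
            build_report(prof, nca_choice, None, rec, "", CLOCK)

    def test_clearance_mismatch_rejected(self, full_run):
        prof, choice, score, rec = full_run
        regimen = Regimen(100.0, 360.0, 10, 16)
        wrong_rec = recommend_dose(
            choice.fit.clearance_l_min * 2, TherapeuticTarget("auc_per_dose", 300.0),
            regimen,
        )
        with pytest.raises(ReportConsistencyError):
            build_report(prof, choice, score, wrong_rec, "", CLOCK)

    def test_deterministic_with_injected_clock(self, full_run):
        prof, choice, score, rec = full_run
        a = build_report(prof, choice, score, rec, "c", CLOCK)
        b = build_report(prof, choice, score, rec, "c", CLOCK)
        assert report_to_json(a) == report_to_json(b)
        assert render_text(a, prof) == render_text(b, prof)


class TestJsonRoundTrip:
    def test_compartmental_round_trip(self, full_run):
        prof, choice, score, rec = full_run
        rpt = build_report(prof, choice, score, rec, "note", CLOCK)
        assert report_from_json(report_to_json(rpt)) == rpt

    def test_nca_round_trip(self, full_run):
        prof, choice, score, rec = full_run
        from bustdm.estimation import override_route

        nca_choice = override_route(choice, "nca", prof)
        res = nca_analyze(prof)
        rec2 = recommend_dose(
            res.clearance_l_min,
            TherapeuticTarget("auc_per_dose", 300.0),
            Regimen(prof.dose.dose_amount_mg, prof.dose.tau_min, 10, 16),
        )
        rpt = build_report(prof, nca_choice, None, rec2, "", CLOCK, nca_result=res)
        assert report_from_json(report_to_json(rpt)) == rpt

    def test_json_schema_field_names_stable(self, full_run):
        """Top-level report schema is pinned: renames break consumers."""
        prof, choice, score, rec = full_run
        rpt = build_report(prof, choice, score, rec, "", CLOCK)
        doc = json.loads(report_to_json(rpt))
        assert sorted(doc) == [
            "comments", "config_digest", "created_at", "fit", "gof", "nca_result",
            "patient_id", "reason_codes", "recommendation", "route", "software_version",
            "study_id",
        ]


class TestRegistry:
    def test_first_report_no_warning(self, full_run, tmp_path):
        prof, choice, score, rec = full_run
        rpt = build_report(prof, choice, score, rec, "", CLOCK)
        reg = ReportRegistry(tmp_path / "reg.jsonl")
        assert register_report(reg, rpt) == {"stored": True, "duplicate_warning": False}
        assert reg.count() == 1

    def test_same_study_warns_but_stores(self, full_run, tmp_path):
        prof, choice, score, rec = full_run
        rpt = build_report(prof, choice, score, rec, "", CLOCK)
        reg = ReportRegistry(tmp_path / "reg.jsonl")
        register_report(reg, rpt)
        status = register_report(reg, rpt)
        assert status == {"stored": True, "duplicate_warning": True}
        assert reg.count() == 2  # append-only audit

    def test_different_study_same_patient_no_warning(self, full_run, tmp_path):
        from dataclasses import replace

        prof, choice, score, rec = full_run
        rpt = build_report(prof, choice, score, rec, "", CLOCK)
        reg = ReportRegistry(tmp_path / "reg.jsonl")
        register_report(reg, rpt)
        other = replace(rpt, study_id="dose13@0")
        assert register_report(reg, other)["duplicate_warning"] is False
        # strict child-only mode warns regardless of study
        assert register_report(reg, other, strict_patient_only=True)[
            "duplicate_warning"
        ] is True


class TestCli:
    def write_profile_csv(self, prof, tmp_path):
        path = tmp_path / "profile.csv"
        write_profile(prof, path, format="csv")
        return str(path)

    def test_fit_command(self, onecpt_profile, tmp_path):
        prof, truth = onecpt_profile
        path = self.write_profile_csv(prof, tmp_path)
        result = CliRunner().invoke(cli_main, ["fit", path, "--format", "json"])
        assert result.exit_code == 0, result.output
        out = json.loads(result.output)
        assert out["route"] == "compartmental_1"
        assert out["clearance_l_min"] == pytest.approx(truth.clearance_l_min, rel=1e-6)
        assert out["gof_band"] == "green"

    def test_simulate_command(self, onecpt_profile, tmp_path):
        prof, truth = onecpt_profile
        path = self.write_profile_csv(prof, tmp_path)
        result = CliRunner().invoke(
            cli_main,
            ["simulate", path, "--target-kind", "auc", "--target-value", "300"],
        )
        assert result.exit_code == 0, result.output
        assert "Recommended dose: 75.00 mg" in result.output

    def test_report_command_warns_on_duplicate(self, onecpt_profile, tmp_path):
        prof, _ = onecpt_profile
        path = self.write_profile_csv(prof, tmp_path)
        reg = str(tmp_path / "reg.jsonl")
        args = [
            "report", path, "--target-kind", "auc", "--target-value", "300",
            "--registry", reg, "--timestamp", CLOCK,
        ]
        runner = CliRunner()
        first = runner.invoke(cli_main, args)
        assert first.exit_code == 0, first.output
        assert "already been submitted" not in first.output
        second = runner.invoke(cli_main, args)
        assert second.exit_code == 0
        assert "already been submitted" in second.output

    def test_generate_command(self, tmp_path):
        out = str(tmp_path / "cohort")
        result = CliRunner().invoke(
            cli_main, ["generate", "--n", "3", "--seed", "5", "--out-dir", out]
        )
        assert result.exit_code == 0, result.output
        truth = json.loads((tmp_path / "cohort" / "truth.json").read_text())
        assert len(truth) == 3

    def test_fit_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("patient_id,conc\nP1,4\n")
        result = CliRunner().invoke(cli_main, ["fit", str(bad)])
        assert result.exit_code == 2
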