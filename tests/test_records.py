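"""Record CSV schema, config/manifest I/O, and command-line interface."""

import json
import subprocess
import sys

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from neoglyc import PatientRecord, ValidationError, read_record, write_record
from neoglyc.cli import main
from neoglyc.records import RECORD_COLUMNS, load_config, write_manifest

from conftest import make_steady_record


@pytest.fixture()
def steady_csv(tmp_path, params):
    record, _ = make_steady_record(params, si=1.5e-3, rate=0.01)
    path = tmp_path / "p001.csv"
    write_record(record, path)
    return record, path


class TestRecordRoundTrip:
    def test_write_read_write_is_byte_identical(self, steady_csv, tmp_path):
        record, path = steady_csv
        loaded = read_record(path)
        path2 = tmp_path / "again.csv"
        write_record(loaded, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_semantic_round_trip(self, steady_csv):
        record, path = steady_csv
        loaded = read_record(path)
        assert loaded.patient_id == "p001"
        assert loaded.weight_kg == record.weight_kg
        np.testing.assert_allclose(loaded.bg_times, record.bg_times)
        np.testing.assert_allclose(loaded.bg_values, record.bg_values)
        assert [m.site for m in loaded.measurements] == \
            [m.site for m in record.measurements]
        for t in np.linspace(0, record.bg_times[-1] - 1e-6, 37):
            assert loaded.insulin.rate_at(t) == record.insulin.rate_at(t)
            assert loaded.glucose_profile().total_at(t) == pytest.approx(
                record.glucose_profile().total_at(t), rel=1e-9)

    def test_header_matches_schema(self, steady_csv):
        _, path = steady_csv
        assert path.read_text().splitlines()[0] == ",".join(RECORD_COLUMNS)


class TestRecordValidation:
    def _rewrite(self, path, mutate):
        lines = path.read_text().splitlines()
        mutate(lines)
        path.write_text("\n".join(lines) + "\n")

    def test_decreasing_time_names_offending_row(self, steady_csv):
        _, path = steady_csv
        self._rewrite(path, lambda L: L.__setitem__(3, "0," + L[3].split(",", 1)[1]))
        with pytest.raises(ValidationError, match="row 4"):
            read_record(path)

    def test_insulin_cap_enforced(self, steady_csv):
        _, path = steady_csv
        def bump(L):
            parts = L[2].split(",")
            parts[3] = "0.6"
            L[2] = ",".join(parts)
        self._rewrite(path, bump)
        with pytest.raises(ValidationError, match="0.5 U/kg/hr cap"):
            read_record(path)

    def test_schema_mismatch_reported(self, steady_csv):
        _, path = steady_csv
        self._rewrite(path, lambda L: L.__setitem__(
            0, L[0].replace("bg_mmol_L", "bg")))
        with pytest.raises(ValidationError, match="schema mismatch"):
            read_record(path)

    def test_out_of_range_bg_names_row(self, steady_csv):
        _, path = steady_csv
        def poison(L):
            parts = L[2].split(",")
            parts[1] = "55.0"
            L[2] = ",".join(parts)
        self._rewrite(path, poison)
        with pytest.raises(ValidationError, match="row 3"):
            read_record(path)

    def test_record_constructor_validates(self):
        from neoglyc import BGMeasurement, InsulinSchedule, NutritionSchedule
        with pytest.raises(ValidationError, match="weight"):
            PatientRecord("p", 0.0, [BGMeasurement(0, 6.0)],
                          InsulinSchedule([0.0], [0.0]), NutritionSchedule([]))


class TestConfigAndManifest:
    def test_load_config_blocks(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({
            "model": {"pG": 0.004, "EGPnet": 3.0},
            "controller": {"setpoint": 6.0, "horizon_choices": [60, 120]},
        }))
        cfg = load_config(path)
        assert cfg["model"].pG == 0.004
        assert cfg["model"].nI == 0.16          # defaults preserved
        assert cfg["controller"].setpoint == 6.0
        assert cfg["controller"].horizon_choices == (60.0, 120.0)

    def test_unknown_controller_option_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"controller": {"stepoint": 6.0}}))
        with pytest.raises(ValidationError, match="stepoint"):
            load_config(path)

    def test_manifest_hashes_inputs(self, tmp_path, steady_csv):
        _, record_path = steady_csv
        out = tmp_path / "manifest.json"
        write_manifest(out, [record_path], seed=42, config_echo={"k": 1})
        m = json.loads(out.read_text())
        assert m["seed"] == 42
        assert len(m["inputs"]) == 1
        digest = next(iter(m["inputs"].values()))
        assert len(digest) == 64


@pytest.fixture(scope="class")
def cli_workspace(tmp_path_factory):
    """One small end-to-end CLI run shared across smoke tests: simulate a
    2-patient sliding-scale trial, then reuse its outputs downstream."""
    root = tmp_path_factory.mktemp("cli")
    spec = root / "spec.yaml"
    spec.write_text(yaml.safe_dump({"n": 2, "duration_h": 24.0}))
    out = root / "trial"
    runner = CliRunner()
    res = runner.invoke(main, ["simulate", "--spec", str(spec),
                               "--protocol", "scale", "--out", str(out),
                               "--seed", "5"], catch_exceptions=False)
    assert res.exit_code == 0, res.output
    return root, out, runner


class TestCLI:
    def test_simulate_writes_records_and_manifest(self, cli_workspace):
        _, out, _ = cli_workspace
        records = sorted(p for p in out.glob("*.csv")
                         if not p.name.endswith(".truth_si.csv"))
        assert len(records) == 2
        assert len(list(out.glob("*.truth_si.csv"))) == 2
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert manifest["config"]["protocol"] == "scale"
        for p in records:
            read_record(p)   # validates

    def test_summarize_json_report(self, cli_workspace):
        root, out, runner = cli_workspace
        report = root / "report.json"
        res = runner.invoke(main, ["summarize", "--records", str(out),
                                   "--truth", str(out), "--out", str(report)],
                            catch_exceptions=False)
        assert res.exit_code == 0, res.output
        d = json.loads(report.read_text())
        assert d["n_patients"] == 2
        assert "pct_bg_4_0_to_8_0" in d
        assert "si_median_L_per_mU_min" in d
        assert (root / "report.manifest.json").exists()

    def test_summarize_markdown_report(self, cli_workspace):
        root, out, runner = cli_workspace
        report = root / "report.md"
        res = runner.invoke(main, ["summarize", "--records", str(out),
                                   "--out", str(report)], catch_exceptions=False)
        assert res.exit_code == 0, res.output
        assert "% BG within 4.0 - 8.0 mmol/L" in report.read_text()

    def test_fit_command(self, cli_workspace):
        root, out, runner = cli_workspace
        record = sorted(p for p in out.glob("*.csv")
                        if not p.name.endswith(".truth_si.csv"))[0]
        si_out = root / "si.csv"
        res = runner.invoke(main, ["fit", "--record", str(record),
                                   "--out", str(si_out)], catch_exceptions=False)
        assert res.exit_code == 0, res.output
        assert "SI median" in res.output
        import pandas as pd
        from neoglyc import SITrace
        trace = SITrace.from_frame(pd.read_csv(si_out))
        assert len(trace) >= 1
        assert (root / "si.manifest.json").exists()

    def test_stochastic_build_and_recommend(self, cli_workspace):
        root, out, runner = cli_workspace
        model_path = root / "model.json"
        res = runner.invoke(main, ["stochastic", "build",
                                   "--synthetic-patients", "10",
                                   "--out", str(model_path), "--seed", "7"],
                            catch_exceptions=False)
        assert res.exit_code == 0, res.output

        record = sorted(p for p in out.glob("*.csv")
                        if not p.name.endswith(".truth_si.csv"))[0]
        audit = root / "audit.jsonl"
        res = runner.invoke(main, ["recommend", "--record", str(record),
                                   "--stochastic", str(model_path),
                                   "--seed", "3", "--audit", str(audit)],
                            catch_exceptions=False)
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert 0.0 <= payload["rate_U_kg_hr"] <= 0.5
        logged = json.loads(audit.read_text().splitlines()[-1])
        assert logged["rate_U_kg_hr"] == payload["rate_U_kg_hr"]

    def test_missing_input_exits_1(self):
        proc = subprocess.run(
            [sys.executable, "-m", "neoglyc.cli", "fit", "--record",
             "no-such-file.csv", "--out", "x.csv"],
            capture_output=True, text=True)
        assert proc.returncode == 1
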