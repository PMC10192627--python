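"""Curve CSV schema, fit-table formatting and the command-line pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from minkin import (
    KineticParameters,
    ModelId,
    ValidationError,
    fit_all,
    fit_report_rows,
    generate_curve,
    generate_study,
    load_preset,
    read_curves_csv,
    write_curves_csv,
    write_fit_table,
    write_markdown_report,
)
from minkin.cli import main as cli_main
from minkin.fitting import FitOutcome
from minkin.study_io import DASH, INF_SENTINEL


class TestCurvesCsv:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "soil,treatment,replicate,time_d,cum_pct\n"
            "S1,B,1,0,0\nS1,B,1,10,5.5\nS1,B,1,120,20.1\n"
        )
        curves = read_curves_csv(path)
        assert len(curves) == 1
        assert curves[0].times.tolist() == [0.0, 10.0, 120.0]
        assert curves[0].provenance == "file"

    def test_round_trip_identity(self, tmp_path, hs_params):
        curves = [
            generate_curve(hs_params, noise_sd=1.0, seed=1, soil="S1", treatment="B"),
            generate_curve(hs_params, noise_sd=1.0, seed=2, soil="S2", treatment="C"),
        ]
        path = tmp_path / "c.csv"
        write_curves_csv(curves, path)
        back = read_curves_csv(path)
        assert len(back) == 2
        for orig, loaded in zip(curves, back):
            np.testing.assert_allclose(loaded.values, orig.values)
            np.testing.assert_allclose(loaded.times, orig.times)

    def test_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "soil,treatment,replicate,time_d,cum_pct\nS1,B,1,0,0\nS1,B,1,10,101\n"
        )
        with pytest.raises(ValidationError, match="\\[0, 100\\]"):
            read_curves_csv(path)

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "soil,treatment,replicate,time_d,cum_pct\nS1,B,1,10,5\nS1,B,1,10,6\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_curves_csv(path)

    def test_non_monotone_beyond_tolerance_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "soil,treatment,replicate,time_d,cum_pct\n"
            "S1,B,1,0,0\nS1,B,1,10,8\nS1,B,1,20,6\n"
        )
        with pytest.raises(ValidationError, match="decrease"):
            read_curves_csv(path)

    def test_small_dips_tolerated(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "soil,treatment,replicate,time_d,cum_pct\n"
            "S1,B,1,0,0\nS1,B,1,10,8\nS1,B,1,20,7.8\n"
        )
        assert len(read_curves_csv(path)) == 1

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("soil,time_d,cum_pct\nS1,0,0\n")
        with pytest.raises(ValidationError, match="missing"):
            read_curves_csv(path)

    def test_ragged_replicates_allowed(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "soil,treatment,replicate,time_d,cum_pct\n"
            "S1,B,1,0,0\nS1,B,1,10,5\nS1,B,2,0,0\n"
        )
        curve = read_curves_csv(path)[0]
        assert curve.replicates == 2
        times, mean = curve.replicate_mean()
        assert times.tolist() == [0.0, 10.0]


class TestFitTable:
    def _outcomes(self):
        curves = generate_study(load_preset("paper", seed=1))[:4]
        return fit_all(curves, seed=1)

    def test_row_rendering(self):
        outcomes = self._outcomes()
        rows = fit_report_rows(outcomes)
        assert len(rows) == len(outcomes)
        for row in rows:
            if row.kinetic_model == "HS":
                assert row.alpha == DASH and row.beta == DASH
            if row.kinetic_model == "FOMC":
                assert row.k1 == DASH and row.k2 == DASH and row.tb == DASH
            if row.kinetic_model == "SFO":
                assert row.k2 == DASH

    def test_dt50_formatting_rules(self):
        outcomes = self._outcomes()
        for row in fit_report_rows(outcomes):
            if row.dt50 == INF_SENTINEL:
                continue
            value = float(row.dt50)
            if value >= 100:
                assert "." not in row.dt50
            else:
                assert row.dt50.count(".") == 1

    def test_infinite_dt50_sentinel(self):
        flat = KineticParameters(model_id=ModelId.SFO, k1=0.0)
        curve = generate_curve(flat, noise_sd=0.0, soil="S", treatment="A")
        out = fit_all([curve], seed=1, models=[ModelId.SFO])
        # flat curve cannot converge; the row renders as failed with dashes
        rows = fit_report_rows(out)
        assert rows[0].kinetic_model == "failed"

    def test_write_csv_and_markdown(self, tmp_path):
        rows = fit_report_rows(self._outcomes())
        csv_path = tmp_path / "t.csv"
        md_path = tmp_path / "t.md"
        write_fit_table(rows, csv_path, format="csv")
        write_fit_table(rows, md_path, format="markdown")
        df = pd.read_csv(csv_path)
        assert len(df) == len(rows)
        assert md_path.read_text().startswith("| soil |")

    def test_report_writer(self, tmp_path):
        curves = generate_study(load_preset("paper", seed=1))[:4]
        outcomes = fit_all(curves, seed=1)
        path = tmp_path / "report.md"
        assays = {"CFU counts": pd.DataFrame({"soil": ["PLD"], "cfu_per_g": [1.5e7]})}
        write_markdown_report(curves, outcomes, path, assay_tables=assays)
        text = path.read_text()
        assert "DT50 ranking" in text
        assert "CFU counts" in text


class TestCli:
    def test_simulate_then_fit_pipeline(self, tmp_path):
        runner = CliRunner()
        curves_csv = tmp_path / "curves.csv"
        table_csv = tmp_path / "table.csv"
        res = runner.invoke(
            cli_main,
            ["simulate", "--preset", "abiotic", "--seed", "1",
             "--out", str(curves_csv)],
        )
        assert res.exit_code == 0
        df = pd.read_csv(curves_csv)
        assert (df["cum_pct"] == 0).all()

    def test_fit_zero_noise_matches_half_life(self, tmp_path):
        """End-to-end: simulated k1=3e-4 soil reports DT50 = ln2/k1."""
        runner = CliRunner()
        curves_csv = tmp_path / "curves.csv"
        curve = generate_curve(
            KineticParameters(model_id=ModelId.SFO, k1=3.0e-4),
            noise_sd=0.0, seed=1, soil="ALC", treatment="B",
        )
        write_curves_csv([curve], curves_csv)
        table_csv = tmp_path / "table.csv"
        res = runner.invoke(
            cli_main,
            ["fit", str(curves_csv), "--model", "sfo", "--seed", "2",
             "--fix-mmax", "--out", str(table_csv)],
        )
        assert res.exit_code == 0
        df = pd.read_csv(table_csv)
        assert float(df.loc[0, "dt50_d"]) == pytest.approx(
            math.log(2) / 3.0e-4, rel=0.01
        )

    def test_validation_error_exit_code(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.csv"
        bad.write_text("soil,treatment\nS,A\n")
        res = runner.invoke(cli_main, ["fit", str(bad)])
        assert res.exit_code == 2

    def test_recover_command_smoke(self):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["recover", "--model", "sfo", "--n-sims", "5", "--seed", "3"],
        )
        assert res.exit_code == 0
        assert "dt50" in res.output
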