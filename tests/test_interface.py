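"""CSV I/O, run configuration, pipeline reproducibility, and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from tempmort.cli import main
from tempmort.config import RunConfig, run_pipeline
from tempmort.io import (
    RegionDataError,
    read_region_csv,
    validate_region,
    write_region_csv,
)
from tempmort.synthetic import TruthScenario, generate_region


@pytest.fixture(scope="module")
def small_region():
    return generate_region(TruthScenario(n_days=500, seed=55))


class TestRegionCSV:
    def test_round_trip_preserves_values(self, small_region, tmp_path):
        path = tmp_path / "region.csv"
        write_region_csv(small_region, path)
        back = read_region_csv(path)
        np.testing.assert_allclose(back["tmean"], small_region["tmean"])
        np.testing.assert_allclose(back["deaths"], small_region["deaths"])
        assert (back["date"] == pd.to_datetime(small_region["date"])).all()

    def test_calendar_columns_reconstructed(self, small_region, tmp_path):
        path = tmp_path / "bare.csv"
        small_region[["date", "deaths", "tmean"]].to_csv(path, index=False)
        back = read_region_csv(path)
        assert (back["dow"] == small_region["dow"]).all()
        assert (back["season"] == small_region["season"]).all()

    def test_date_gap_rejected(self, small_region):
        broken = small_region.drop(index=10)
        with pytest.raises(RegionDataError, match="gap"):
            validate_region(broken)

    def test_unsorted_dates_rejected(self, small_region):
        shuffled = small_region.iloc[::-1].reset_index(drop=True)
        with pytest.raises(RegionDataError, match="increasing"):
            validate_region(shuffled)

    def test_negative_deaths_rejected(self, small_region):
        bad = small_region.copy()
        bad.loc[40, "deaths"] = -1
        with pytest.raises(RegionDataError, match="negative"):
            validate_region(bad)

    def test_fractional_deaths_rejected(self, small_region):
        bad = small_region.copy()
        bad.loc[40, "deaths"] = 2.5
        with pytest.raises(RegionDataError, match="integer"):
            validate_region(bad)

    def test_temperature_ordering_violation_named(self, small_region):
        bad = small_region.copy()
        bad.loc[40, "tmin"] = bad.loc[40, "tmax"] + 5
        with pytest.raises(RegionDataError, match="tmin <= tmean <= tmax"):
            validate_region(bad)

    def test_missing_required_column_rejected(self, small_region):
        with pytest.raises(RegionDataError, match="missing required"):
            validate_region(small_region.drop(columns=["tmean"]))


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 7\nn_boot: 10\nseason: winter\n")
        cfg = RunConfig.from_yaml(path)
        assert cfg.seed == 7 and cfg.n_boot == 10 and cfg.season == "winter"
        assert cfg.m == 500  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seeed: 7\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_yaml(path)

    def test_hash_depends_on_content(self):
        assert RunConfig(seed=1).hash != RunConfig(seed=2).hash
        assert RunConfig(seed=1).hash == RunConfig(seed=1).hash


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipe")
    cfg = RunConfig(
        n_days=1500, full_grid=False, n_boot=10, m=25, n_s=700, seed=3,
        outdir=str(outdir),
    )
    summary = run_pipeline(cfg)
    return cfg, outdir, summary


class TestPipeline:
    def test_summary_has_all_stage_blocks(self, pipeline_run):
        _, _, summary = pipeline_run
        assert {"data", "bias_correction", "selection", "prediction",
                "validation", "simulation_study"} <= set(summary)
        assert summary["simulation_study"]["scaled"] is True

    def test_artefacts_written(self, pipeline_run):
        _, outdir, _ = pipeline_run
        for name in (
            "observed.csv", "simulated.csv", "corrected.csv", "quantile_map.csv",
            "model_ranking.csv", "cumulative_curve.csv", "lag_curve.csv",
            "rr_surface.csv", "validation.json", "bias_histogram.csv",
            "simulation_study.csv", "summary.json",
        ):
            assert (outdir / name).exists(), name

    def test_bias_correction_reduces_decile_error(self, pipeline_run):
        _, _, summary = pipeline_run
        bc = summary["bias_correction"]
        assert bc["mean_abs_decile_error_corrected"] < bc["mean_abs_decile_error_raw"]

    def test_rerun_is_byte_identical(self, pipeline_run, tmp_path):
        cfg, outdir, _ = pipeline_run
        cfg2 = RunConfig(**{**cfg.to_dict(), "outdir": str(tmp_path / "again")})
        run_pipeline(cfg2)
        first = json.loads((outdir / "summary.json").read_text())
        second = json.loads((tmp_path / "again" / "summary.json").read_text())
        # outdir is part of the config echo; everything else must match
        first["config"].pop("outdir")
        second["config"].pop("outdir")
        first.pop("config_hash")
        second.pop("config_hash")
        assert first == second
        assert (outdir / "cumulative_curve.csv").read_bytes() == (
            tmp_path / "again" / "cumulative_curve.csv"
        ).read_bytes()

    def test_summary_json_matches_return_value(self, pipeline_run):
        _, outdir, summary = pipeline_run
        on_disk = json.loads((outdir / "summary.json").read_text())
        assert on_disk == json.loads(json.dumps(summary, sort_keys=True))


class TestCLI:
    def test_simulate_data_writes_valid_csv(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "r.csv"
        twin = tmp_path / "d.csv"
        result = runner.invoke(
            main,
            ["simulate-data", "--n-days", "200", "--seed", "1",
             "--out", str(out), "--distorted-out", str(twin)],
        )
        assert result.exit_code == 0, result.output
        region = read_region_csv(out)
        assert len(region) == 200
        assert read_region_csv(twin)["tmean"].mean() > region["tmean"].mean()

    def test_bias_correct_command(self, tmp_path):
        runner = CliRunner()
        obs, sim, out = (tmp_path / n for n in ("o.csv", "s.csv", "c.csv"))
        runner.invoke(main, ["simulate-data", "--n-days", "800", "--seed", "2",
                             "--out", str(obs), "--distorted-out", str(sim)])
        result = runner.invoke(
            main,
            ["bias-correct", "--observed", str(obs), "--simulated", str(sim),
             "--out", str(out), "--table-out", str(tmp_path / "t.csv")],
        )
        assert result.exit_code == 0, result.output
        corrected = read_region_csv(out)
        observed = read_region_csv(obs)
        raw = read_region_csv(sim)
        err_c = abs(corrected["tmean"].median() - observed["tmean"].median())
        err_r = abs(raw["tmean"].median() - observed["tmean"].median())
        assert err_c < err_r
        assert (tmp_path / "t.csv").exists()

    def test_simstudy_command_small(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim.csv"
        result = runner.invoke(
            main, ["simstudy", "--m", "10", "--n-s", "600", "--seed", "4",
                   "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out)
        assert list(table.columns) == [
            "model_id", "label", "bias_pct", "coverage", "rmse_pct", "effective_m"
        ]
        assert len(table) == 1
        assert 0.0 <= table.loc[0, "coverage"] <= 1.0

    def test_help_lists_subcommands(self):
        result = CliRunner().invoke(main, ["--help"])
        assert result.exit_code == 0
        for cmd in ("simulate-data", "bias-correct", "select", "predict",
                    "validate", "simstudy", "all"):
            assert cmd in result.output
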