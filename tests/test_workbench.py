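"""The synthetic-data generator and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import greycast as gc
from greycast.cli import main


class TestSimulate:
    def test_same_seed_is_identical(self):
        spec = gc.SimulationSpec(noise_sd=0.05, seed=42)
        s1, d1, _ = gc.simulate(spec)
        s2, d2, _ = gc.simulate(spec)
        assert (s1.values == s2.values).all()
        assert (d1[0].values == d2[0].values).all()

    def test_different_seeds_differ_under_noise(self):
        s1, _, _ = gc.simulate(gc.SimulationSpec(noise_sd=0.05, seed=1))
        s2, _, _ = gc.simulate(gc.SimulationSpec(noise_sd=0.05, seed=2))
        assert not np.allclose(s1.values, s2.values)

    def test_noiseless_linear_case_recovers_by_ols(self):
        spec = gc.SimulationSpec(n=15, a=-0.06, b=(0.95,), gamma=(1.0,), noise_sd=0.0, seed=9)
        system, drivers, truth = gc.simulate(spec)
        r = gc.fit_gm1n(gc.prepare(system, drivers))
        assert r.params.a == pytest.approx(truth.a, abs=1e-9)
        assert r.params.b[0] == pytest.approx(truth.b[0], abs=1e-9)

    def test_system_starts_at_one_and_stays_positive(self):
        system, drivers, _ = gc.simulate(gc.SimulationSpec(seed=3, noise_sd=0.02))
        assert system.values[0] == 1.0
        assert (system.values > 0).all()
        assert (np.diff(drivers[0].values) > 0).all()  # geometric growth

    def test_inadmissible_parameters_are_rejected(self):
        with pytest.raises(gc.SimulationError):
            gc.simulate(gc.SimulationSpec(a=-0.1, b=(-5.0,), gamma=(1.0,)))

    def test_explicit_driver_paths(self):
        paths = np.linspace(1, 3, 10).reshape(-1, 1)
        spec = gc.SimulationSpec(n=10, driver_paths=paths)
        _, drivers, _ = gc.simulate(spec)
        assert drivers[0].values == pytest.approx(paths[:, 0])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            gc.SimulationSpec(n=3)
        with pytest.raises(ValueError):
            gc.SimulationSpec(noise_sd=-1.0)
        with pytest.raises(ValueError):
            gc.SimulationSpec(b=(1.0, 2.0), gamma=(0.5,))


@pytest.fixture
def runner():
    return CliRunner()


class TestCliFit:
    def test_gm_fit_on_packaged_data_reports_coefficients(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["fit", "--fixture", "--model", "gm1n", "--system", "WDPC",
             "--drivers", "GDP", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        assert "a=-0.197102" in result.output
        report = json.loads((tmp_path / "WDPC_gm1n_report.json").read_text())
        assert report["params"]["a"] == pytest.approx(-0.1971, abs=1e-4)
        assert report["params"]["b"][0] == pytest.approx(-0.04553, abs=1e-4)
        assert (tmp_path / "WDPC_gm1n_fitted.csv").exists()

    def test_nls_fit_nonconvergence_warns_but_exits_zero(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["fit", "--fixture", "--model", "tngm1n", "--system", "WDPC",
             "--drivers", "GDP", "--max-iter", "5", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0
        assert "did not converge" in result.output
        assert (tmp_path / "WDPC_tngm1n_trace.csv").exists()

    def test_strict_nonconvergence_exits_nonzero(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["fit", "--fixture", "--model", "tngm1n", "--system", "WDPC",
             "--drivers", "GDP", "--max-iter", "5", "--strict", "--out", str(tmp_path)],
        )
        assert result.exit_code == 2

    def test_missing_column_is_usage_error(self, runner, tmp_path):
        result = runner.invoke(
            main, ["fit", "--fixture", "--system", "NOPE", "--drivers", "GDP",
                   "--out", str(tmp_path)],
        )
        assert result.exit_code != 0

    def test_empty_csv_is_usage_error(self, runner, tmp_path):
        bad = tmp_path / "empty.csv"
        bad.write_text("Year\n")
        result = runner.invoke(
            main, ["fit", "--input", str(bad), "--system", "y", "--drivers", "x"],
        )
        assert result.exit_code != 0

    def test_reports_are_byte_identical_across_runs(self, runner, tmp_path):
        for d in ("one", "two"):
            res = runner.invoke(
                main, ["fit", "--fixture", "--system", "SO2", "--drivers", "GDP",
                       "--out", str(tmp_path / d)],
            )
            assert res.exit_code == 0
        a = (tmp_path / "one" / "SO2_gm1n_report.json").read_bytes()
        b = (tmp_path / "two" / "SO2_gm1n_report.json").read_bytes()
        assert a == b

    def test_config_file_supplies_defaults(self, runner, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "fit:\n  system: WDPC\n  drivers: GDP\n  fixture: true\n"
            f"  out_dir: {tmp_path}\n"
        )
        result = runner.invoke(main, ["--config", str(cfg), "fit"])
        assert result.exit_code == 0, result.output
        assert "a=-0.197102" in result.output


class TestCliForecast:
    def test_horizon_zero_echoes_in_sample(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["forecast", "--fixture", "--model", "gm1n", "--system", "WDPC",
             "--drivers", "GDP", "--horizon", "0", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        import pandas as pd

        frame = pd.read_csv(tmp_path / "WDPC_gm1n_forecast.csv")
        assert len(frame) == 20 and frame["InSample"].all()
        assert frame["Accumulated"].iloc[0] == pytest.approx(1.0)

    def test_growth_assumption_extends_horizon(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["forecast", "--fixture", "--model", "gm1n", "--system", "WDPC",
             "--drivers", "GDP", "--horizon", "3", "--driver-growth", "0.08",
             "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        import pandas as pd

        frame = pd.read_csv(tmp_path / "WDPC_gm1n_forecast.csv")
        assert len(frame) == 23 and (~frame["InSample"]).sum() == 3
        assert frame["Year"].iloc[-1] == 2018
        meta = json.loads((tmp_path / "WDPC_gm1n_forecast_meta.json").read_text())
        assert "recursion" in meta["convention"]

    def test_missing_driver_future_is_an_error(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["forecast", "--fixture", "--system", "WDPC", "--drivers", "GDP",
             "--horizon", "2", "--out", str(tmp_path)],
        )
        assert result.exit_code != 0
        assert "driver-future" in result.output or "driver-growth" in result.output


class TestCliCompare:
    def test_fixture_comparison_declares_nonlinear_winner(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["compare", "--fixture", "--system", "WDPC", "--drivers", "GDP",
             "--tol", "1e-8", "--max-iter", "3000", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        summary = json.loads((tmp_path / "WDPC_comparison.json").read_text())
        assert summary["winner"] == "tngm1n"
        assert summary["models"]["gm1n"]["mape_exclude_base"] == pytest.approx(20.80, abs=0.01)
        assert (tmp_path / "WDPC_comparison.csv").exists()


class TestCliSimulate:
    def test_writes_table_and_truth(self, runner, tmp_path):
        result = runner.invoke(
            main,
            ["simulate", "--n", "12", "--noise-sd", "0.01", "--seed", "7",
             "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        table = gc.read_csv(tmp_path / "simulated.csv")
        assert set(table) == {"system", "driver2"} and len(table["system"]) == 12
        truth = json.loads((tmp_path / "simulated_truth.json").read_text())
        assert truth["seed"] == 7 and truth["a"] == pytest.approx(-0.0426)

    def test_simulate_then_fit_round_trip(self, runner, tmp_path):
        assert runner.invoke(
            main, ["simulate", "--n", "16", "--seed", "4", "--out", str(tmp_path)]
        ).exit_code == 0
        result = runner.invoke(
            main,
            ["fit", "--input", str(tmp_path / "simulated.csv"), "--model", "tngm1n",
             "--system", "system", "--drivers", "driver2", "--tol", "1e-9",
             "--max-iter", "3000", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        report = json.loads((tmp_path / "system_tngm1n_report.json").read_text())
        assert report["params"]["a"] == pytest.approx(-0.0426, abs=1e-4)
        assert report["params"]["gamma"][0] == pytest.approx(-0.099, abs=1e-3)
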