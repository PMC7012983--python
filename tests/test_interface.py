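"""Configuration, fixtures, I/O and the CLI shell."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import structpop as sp
from structpop.cli import main
from structpop.config import compile_rate, load_model, parse_weight, parse_weight_list
from structpop.fixtures import EnvironmentScript, FixtureSpec, make_environment, make_history
from structpop.io import read_series, sidecar_path, write_series

MONOD_CFG = """
name: monod
params: {a: 1.0, b: 1.0, D: 0.5, beta_c: 0.5}
istate: {x_min: 0.0001220703125, x_max: 8192.0}
rates:
  g: "(a*S/(b+S))*x"
  mu: "beta_c + D"
birth_kernel:
  form: fission
  beta0: "beta_c"
environment:
  mode: prescribed
  value: "1.0"
initial: {shape: point, state: 1.0, total_mass: 1.0}
run: {horizon: 2.0, dt: 0.01, merge_dx: 0.002}
"""

CATALOGUE_CFG = """
istate: {x_min: 0.2, x_max: 3.0}
catalogue:
  family: F3
  k: 2
  v0: "1"
  v1: "2"
  v2: "-0.5"
  mu0: "0.1"
  x_b: 0.2
"""


class TestExpressions:
    def test_expression_and_callable_paths_agree(self):
        # the same rate given as an expression and as a python callable
        expr = compile_rate("(a*S/(b+S))*x", {"a": 1.0, "b": 1.0})
        fn = lambda x, S: (1.0 * S / (1.0 + S)) * x
        xs = np.geomspace(0.1, 10, 50)
        for S in (0.3, 1.0, 4.0):
            assert np.allclose(expr(xs, S), fn(xs, S), rtol=1e-14)

    def test_S_is_an_alias_for_E(self):
        f = compile_rate("S*x")
        assert f(np.array([2.0]), 3.0)[0] == 6.0

    def test_unknown_names_rejected(self):
        with pytest.raises(sp.ConfigError, match="unknown names"):
            compile_rate("q*x")

    def test_arbitrary_code_not_evaluated(self):
        with pytest.raises(sp.ConfigError):
            compile_rate("__import__('os').system('true')")

    def test_weight_derivative_is_symbolic(self):
        w = parse_weight("x**(2/3)")
        xs = np.geomspace(0.1, 10, 30)
        assert np.allclose(w.d(xs), (2.0 / 3.0) * xs ** (-1.0 / 3.0), rtol=1e-12)

    def test_weight_list_splits_at_top_level_commas(self):
        ws = parse_weight_list("x, Max(x, 1), x**(2/3)")
        assert len(ws) == 3


class TestModelLoading:
    def test_monod_config_round_trip(self):
        bundle = load_model(MONOD_CFG)
        assert bundle.model.space.birth_state is None
        xs = np.geomspace(0.1, 10, 20)
        assert np.allclose(bundle.model.rates.g(xs, 1.0), 0.5 * xs)
        assert np.allclose(bundle.model.rates.mu(xs, 1.0), 1.0)
        assert bundle.environment.at(17.0) == 1.0

    def test_catalogue_config_builds_and_verifies(self):
        bundle = load_model(CATALOGUE_CFG)
        cm = bundle.model.meta["catalogue"]
        assert cm.family == "F3"
        assert cm.verification_residual < 1e-10

    def test_missing_section_is_a_config_error(self):
        with pytest.raises(sp.ConfigError):
            load_model("istate: {x_min: 0.1, x_max: 1.0, birth_state: 0.5}")


class TestFixtures:
    def test_point_cohort(self):
        h = make_history(FixtureSpec(shape="point", state=1.5, total_mass=2.0))
        assert len(h.atoms) == 1
        assert h.atoms[0].state == 1.5 and h.atoms[0].mass == 2.0

    def test_uniform_band_equal_masses(self):
        h = make_history(FixtureSpec(shape="uniform_band", n_atoms=10,
                                     total_mass=1.0, state_lo=0.5, state_hi=2.0))
        masses = [a.mass for a in h.atoms]
        assert len(masses) == 10
        assert np.allclose(masses, 0.1)

    def test_gaussian_total_mass_exact(self):
        h = make_history(FixtureSpec(shape="gaussian", n_atoms=100, total_mass=3.0,
                                     state_lo=0.2, state_hi=2.5, mean=1.0, sigma=0.3))
        assert h.total_mass == pytest.approx(3.0, abs=1e-10)

    def test_negative_mass_rejected(self):
        with pytest.raises(sp.ConfigError):
            FixtureSpec(total_mass=-1.0)

    def test_environment_scripts(self):
        step = make_environment(EnvironmentScript(kind="step", value=1.0,
                                                  value_after=2.0, t_step=1.0))
        assert step.at(0.5) == 1.0 and step.at(1.5) == 2.0
        stored = make_environment(EnvironmentScript(
            kind="stored", t_values=np.array([0.0, 1.0]), E_values=np.array([0.0, 2.0])))
        assert stored.at(0.5) == 1.0


class TestSeriesIO:
    def test_round_trip_is_lossless_to_printed_precision(self, tmp_path):
        df = pd.DataFrame({"t": np.linspace(0, 1, 7),
                           "X": np.exp(np.linspace(0, 1, 7)) * np.pi})
        p = write_series(df, tmp_path / "s.csv", {"config_hash": "abc"})
        back, meta = read_series(p, required_columns=["t", "X"])
        assert np.allclose(back["X"], df["X"], rtol=1e-11)
        assert meta["config_hash"] == "abc"

    def test_missing_column_named(self, tmp_path):
        df = pd.DataFrame({"t": [0.0, 1.0]})
        p = write_series(df, tmp_path / "s.csv")
        with pytest.raises(sp.ConfigError, match="'X'"):
            read_series(p, required_columns=["X"])

    def test_hash_mismatch_flagged(self, tmp_path):
        df = pd.DataFrame({"t": [0.0]})
        p = write_series(df, tmp_path / "s.csv", {"config_hash": "abc"})
        with pytest.raises(sp.ConfigError, match="hash"):
            read_series(p, expect_hash="other")

    def test_deterministic_bytes(self, tmp_path):
        df = pd.DataFrame({"t": np.linspace(0, 1, 5), "X": np.sqrt(np.linspace(1, 2, 5))})
        p1 = write_series(df, tmp_path / "a.csv")
        p2 = write_series(df, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()


class TestCLI:
    def test_simulate_writes_series_and_sidecar(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(MONOD_CFG)
        out = tmp_path / "series.csv"
        res = CliRunner().invoke(main, ["simulate", "--model", str(cfg),
                                        "--out", str(out)])
        assert res.exit_code == 0, res.output
        df, meta = read_series(out, required_columns=["t", "E", "total_biomass"])
        assert len(df) == 201
        assert "config_hash" in meta

    def test_reduce_check_reducible_model(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(MONOD_CFG)
        rep = tmp_path / "report.json"
        res = CliRunner().invoke(main, ["reduce-check", "--model", str(cfg),
                                        "--weights", "x", "--report", str(rep)])
        assert res.exit_code == 0, res.output
        data = json.loads(rep.read_text())
        assert data["verdict"] == "reducible"
        assert "k1" in data

    def test_reduce_check_not_reducible_is_still_exit_zero(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(MONOD_CFG.replace('g: "(a*S/(b+S))*x"', 'g: "S*x**2"'))
        rep = tmp_path / "report.json"
        res = CliRunner().invoke(main, ["reduce-check", "--model", str(cfg),
                                        "--weights", "x", "--report", str(rep)])
        assert res.exit_code == 0, res.output
        assert json.loads(rep.read_text())["verdict"] == "not reducible"

    def test_invalid_tolerance_exit_code_2(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(MONOD_CFG)
        res = CliRunner().invoke(main, ["reduce-check", "--model", str(cfg),
                                        "--weights", "x", "--tol", "-1",
                                        "--report", str(tmp_path / "r.json")])
        assert res.exit_code == 2

    def test_catalogue_verify_and_emit(self, tmp_path):
        cfg = tmp_path / "params.yaml"
        cfg.write_text(CATALOGUE_CFG)
        out = tmp_path / "model.yaml"
        res = CliRunner().invoke(main, ["catalogue", "--family", "F3",
                                        "--params", str(cfg), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert load_model(str(out)).model.meta["catalogue"].k == 2

    def test_unknown_subcommand_usage_error(self):
        res = CliRunner().invoke(main, ["frobnicate"])
        assert res.exit_code == 2
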