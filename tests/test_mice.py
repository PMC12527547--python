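import numpy as np
import pandas as pd
import pytest

from hiermice.data_model import IPDataset, VariableSpec
from hiermice.imputers import ImputerConfig, impute_mlmi
from hiermice.mice import MiceConfig, MiceError, _visit_order, initial_fill, run_mice
from hiermice.synthetic import SimConfig, generate_ipd, impose_sporadic, make_incomplete

SPEC = [
    VariableSpec("study", "cluster_id", "cluster"),
    VariableSpec("x1", "binary", "covariate"),
    VariableSpec("x2", "count", "covariate"),
    VariableSpec("y", "continuous", "outcome"),
]


@pytest.fixture(scope="module")
def small_incomplete():
    cfg = SimConfig(outcome_type="binary", n_studies=6, per_study=60,
                    pi_systematic=0.10, seed=17)
    _, inc, _ = make_incomplete(cfg)
    return inc


class TestInitialFill:
    def test_constant_variable_fills_with_constant(self, rng):
        df = pd.DataFrame(
            {"study": ["a"] * 4 + ["b"] * 4,
             "x1": [1.0, 1.0, np.nan, 1.0, np.nan, 1.0, 1.0, np.nan],
             "x2": [1.0] * 8, "y": np.arange(8.0)}
        )
        ds = IPDataset(df, SPEC)
        out = initial_fill(ds, rng)
        assert (out.data["x1"] == 1.0).all()

    def test_fills_respect_domain(self, small_incomplete, rng):
        out = initial_fill(small_incomplete, rng)
        assert not out.data[out.variables()].isna().any().any()
        assert set(out.data["x1"].unique()) <= {0.0, 1.0}

    def test_within_study_frequencies(self, rng):
        # study 'a' observes only ones, study 'b' observes 30% ones: the
        # fill distribution must track each study's own observed frequency
        df = pd.DataFrame(
            {"study": ["a"] * 200 + ["b"] * 200,
             "x1": [1.0] * 100 + [np.nan] * 100
                   + [1.0] * 30 + [0.0] * 70 + [np.nan] * 100,
             "x2": [1.0] * 400, "y": np.zeros(400)}
        )
        ds = IPDataset(df, SPEC)
        fills_a, fills_b = [], []
        for k in range(10):
            out = initial_fill(ds, np.random.default_rng(k))
            fills_a.append(out.data.loc[100:199, "x1"].mean())
            fills_b.append(out.data.loc[300:399, "x1"].mean())
        assert np.mean(fills_a) == pytest.approx(1.0, abs=1e-12)
        assert np.mean(fills_b) == pytest.approx(0.3, abs=0.05)

    def test_unobserved_variable_raises(self, rng):
        df = pd.DataFrame(
            {"study": ["a", "b"], "x1": [np.nan, np.nan],
             "x2": [1.0, 2.0], "y": [0.0, 1.0]}
        )
        with pytest.raises(MiceError):
            initial_fill(IPDataset(df, SPEC), rng)


class TestRunMice:
    def test_complete_data_is_noop(self):
        cfg = SimConfig(outcome_type="binary", n_studies=4, per_study=40, seed=3)
        ds, _ = generate_ipd(cfg)
        stack = run_mice(ds, MiceConfig(m=3, cycles=2, outcome="y", seed=1))
        assert stack.m == 3
        assert all(d.equals(ds) for d in stack.completed)
        assert stack.chain_log.empty

    def test_identical_seed_bit_identical(self, small_incomplete):
        cfg = MiceConfig(m=2, cycles=3,
                         method_map={"x1": "mlmi", "x2": "mlmi"},
                         outcome="y", seed=99)
        s1 = run_mice(small_incomplete, cfg)
        s2 = run_mice(small_incomplete, cfg)
        for a, b in zip(s1.completed, s2.completed):
            pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(s1.chain_log, s2.chain_log)

    def test_observed_cells_never_change(self, small_incomplete):
        cfg = MiceConfig(m=2, cycles=2,
                         method_map={"x1": "mlmi", "x2": "mlmi"},
                         outcome="y", seed=5)
        stack = run_mice(small_incomplete, cfg)
        for d in stack.completed:
            assert not d.data[d.variables()].isna().any().any()
            for var in ("x1", "x2"):
                obs = small_incomplete.data[var].notna()
                assert d.data.loc[obs, var].equals(
                    small_incomplete.data.loc[obs, var]
                )

    def test_uncovered_variable_raises(self, small_incomplete):
        with pytest.raises(MiceError, match="method"):
            run_mice(small_incomplete,
                     MiceConfig(m=1, cycles=1, method_map={"x1": "mlmi"},
                                outcome="y"))

    def test_visit_order_sorts_by_missing_fraction(self, rng):
        df = pd.DataFrame(
            {"study": ["a"] * 10 + ["b"] * 10,
             "x1": [np.nan] * 8 + [0.0, 1.0] + [1.0] * 10,
             "x2": [np.nan, 1.0] * 10,
             "y": np.arange(20.0)}
        )
        ds = IPDataset(df, SPEC)
        order = _visit_order(ds, MiceConfig(), ["x1", "x2"])
        assert order == ["x1", "x2"]  # 40% missing before 50% missing

    def test_single_variable_reduction_matches_elementary_imputer(self):
        """With one incomplete variable, a chain reduces to repeated calls
        of its elementary imputer; the final-draw means must agree."""
        cfg = SimConfig(outcome_type="binary", n_studies=6, per_study=50, seed=23)
        ds, _ = generate_ipd(cfg)
        inc = impose_sporadic(ds, "x2", "MCAR", 0.2, 0.0,
                              np.random.default_rng(11))
        miss = inc.data["x2"].isna()
        engine_means, direct_means = [], []
        icfg = ImputerConfig("poisson", ("intercept", "y"))
        for k in range(100):
            stack = run_mice(inc, MiceConfig(m=1, cycles=3,
                                             method_map={"x2": "mlmi"},
                                             outcome="y", seed=k))
            engine_means.append(stack.completed[0].data.loc[miss, "x2"].mean())
            # predictors are complete, so every cycle sees the same inputs:
            # the chain reduces to repeated elementary calls, last one kept
            rng = np.random.default_rng(10_000 + k)
            for _ in range(3):
                col = impute_mlmi(inc, "x2", ("x1", "y"), icfg, rng)
            direct_means.append(col[miss].mean())
        se = np.sqrt(np.var(engine_means, ddof=1) / 100
                     + np.var(direct_means, ddof=1) / 100)
        assert abs(np.mean(engine_means) - np.mean(direct_means)) < 3.5 * se


class TestSerialization:
    def test_save_roundtrip(self, small_incomplete, tmp_path):
        import json

        cfg = MiceConfig(m=2, cycles=1,
                         method_map={"x1": "mlmi", "x2": "mlmi"},
                         outcome="y", seed=7)
        stack = run_mice(small_incomplete, cfg)
        stack.save(tmp_path / "out")
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["m"] == 2 and len(manifest["files"]) == 2
        assert (tmp_path / "out" / "imputed_1.csv").exists()
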