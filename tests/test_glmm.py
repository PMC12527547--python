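import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from hiermice.data_model import IPDataset, VariableSpec
from hiermice.glmm import (
    EstimationError,
    GLMMSpec,
    cluster_loglik,
    fit_glmm,
    max_cluster_loglik,
)
from hiermice.synthetic import SimConfig, TrueParams, generate_ipd

BSPEC = GLMMSpec("binomial", "z", ("x",), "study", ("intercept",))
PSPEC = GLMMSpec("poisson", "z", ("x",), "study", ("intercept",))
GSPEC = GLMMSpec("gaussian", "z", ("x",), "study", ("intercept",))


def _rows(z, x):
    return pd.DataFrame({"z": z, "x": x, "study": "s"})


class TestClusterLoglik:
    def test_bernoulli_closed_form(self):
        # one row, z=1, eta=0 -> log 0.5
        ll = cluster_loglik(np.zeros(2), np.zeros(1), BSPEC, _rows([1.0], [0.3]))
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_poisson_closed_form(self):
        # one row, z=2, eta=0 -> -1 - log 2!
        ll = cluster_loglik(np.zeros(2), np.zeros(1), PSPEC, _rows([2.0], [0.0]))
        assert ll == pytest.approx(-1.0 - np.log(2.0), abs=1e-12)

    def test_additivity_over_rows(self, rng):
        z = rng.binomial(1, 0.4, size=6).astype(float)
        x = rng.normal(size=6)
        beta, b = np.array([0.2, -0.5]), np.array([0.3])
        total = cluster_loglik(beta, b, BSPEC, _rows(z, x))
        parts = sum(
            cluster_loglik(beta, b, BSPEC, _rows([zi], [xi])) for zi, xi in zip(z, x)
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            cluster_loglik(np.zeros(2), np.zeros(2), BSPEC, _rows([1.0], [0.0]))

    def test_empty_cluster_is_zero(self):
        assert cluster_loglik(np.zeros(2), np.zeros(1), BSPEC, _rows([], [])) == 0.0


class TestMaxClusterLoglik:
    def test_gaussian_matches_least_squares_oracle(self, rng):
        # identity random design: maximizer solves ordinary least squares of
        # the beta-residual on Z
        n = 20
        x = rng.normal(size=n)
        z = 0.5 + 0.3 * x + rng.normal(size=n)
        beta = np.array([0.1, 0.2])
        spec = GLMMSpec("gaussian", "z", ("x",), "study", ("intercept", "x"))
        rows = _rows(z, x)
        b_num, ll_num = max_cluster_loglik(beta, spec, rows)
        Z = np.column_stack([np.ones(n), x])
        resid = z - Z @ beta
        b_ls, *_ = np.linalg.lstsq(Z, resid, rcond=None)
        assert np.allclose(b_num, b_ls, atol=1e-6)

    def test_empty_cluster_convention(self):
        b, ll = max_cluster_loglik(np.zeros(2), BSPEC, _rows([], []))
        assert ll == 0.0 and np.all(b == 0.0)

    def test_maximum_dominates_random_points(self, rng):
        """loglik_max >= loglik at 50 random b, for 20 random clusters."""
        for _ in range(20):
            fam = rng.choice(["binomial", "poisson", "gaussian"])
            spec = GLMMSpec(fam, "z", ("x",), "study", ("intercept",))
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            eta = 0.2 + 0.1 * x
            if fam == "binomial":
                z = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            elif fam == "poisson":
                z = rng.poisson(np.exp(eta)).astype(float)
            else:
                z = eta + rng.normal(size=n)
            rows = _rows(z, x)
            beta = rng.normal(size=2) * 0.5
            _, ll_max = max_cluster_loglik(beta, spec, rows)
            for b in rng.normal(size=(50, 1)):
                assert ll_max >= cluster_loglik(beta, b, spec, rows) - 1e-8


class TestFitGlmm:
    def test_gaussian_matches_mixedlm_reference(self, continuous_ipd):
        """Dual-route check: our Laplace-EM vs statsmodels MixedLM (ML)."""
        ds, _ = continuous_ipd
        spec = GLMMSpec(
            "gaussian", "y", ("x1", "x2"), "study", ("intercept", "x1")
        )
        fit = fit_glmm(ds, spec, tol=1e-8)
        ref = smf.mixedlm(
            "y ~ x1 + x2", ds.data, groups=ds.data["study"], re_formula="~x1"
        ).fit(reml=False, method="lbfgs")
        assert np.allclose(fit.beta_hat, ref.fe_params.values, atol=1e-3)
        assert np.allclose(fit.Omega_hat, ref.cov_re.values, atol=1e-3)
        assert fit.sigma2_hat == pytest.approx(ref.scale, abs=1e-3)
        assert np.allclose(
            np.sqrt(np.diag(fit.V_beta)), ref.bse_fe.values, atol=1e-3
        )

    def test_degenerate_no_heterogeneity_reduces_to_ols(self, rng):
        truth = TrueParams(tau=(0.0, 0.0, 0.0), psi=np.zeros((2, 2)))
        cfg = SimConfig(outcome_type="continuous", n_studies=20, per_study=150,
                        seed=5)
        ds, _ = generate_ipd(cfg, rng, truth=truth)
        spec = GLMMSpec(
            "gaussian", "y", ("x1", "x2"), "study", ("intercept", "x1")
        )
        fit = fit_glmm(ds, spec, tol=1e-8)
        X = np.column_stack(
            [np.ones(len(ds.data)), ds.data["x1"], ds.data["x2"]]
        )
        ols, *_ = np.linalg.lstsq(X, ds.data["y"].to_numpy(), rcond=None)
        assert np.allclose(fit.beta_hat, ols, atol=1e-3)
        assert np.all(np.diag(fit.Omega_hat) < 5e-3)

    def test_binomial_recovers_generating_fixed_effects(self):
        cfg = SimConfig(outcome_type="binary", n_studies=30, per_study=500,
                        heterogeneity="moderate", seed=7)
        ds, truth = generate_ipd(cfg)
        spec = GLMMSpec(
            "binomial", "y", ("x1", "x2"), "study", ("intercept", "x1")
        )
        fit = fit_glmm(ds, spec)
        assert fit.converged
        assert np.all(np.abs(fit.beta_hat - np.array(truth.beta)) < 0.1)

    def test_single_cluster_raises(self):
        df = pd.DataFrame(
            {"study": ["a"] * 30, "x1": [0.0, 1.0] * 15,
             "x2": [1.0] * 30, "y": np.arange(30.0)}
        )
        spec = [
            VariableSpec("study", "cluster_id", "cluster"),
            VariableSpec("x1", "binary", "covariate"),
            VariableSpec("x2", "count", "covariate"),
            VariableSpec("y", "continuous", "outcome"),
        ]
        ds = IPDataset(df, spec)
        with pytest.raises(EstimationError):
            fit_glmm(ds, GLMMSpec("poisson", "x2", ("x1", "y"), "study"))

    def test_rows_with_missing_predictors_excluded(self, binary_ipd):
        _, incomplete, _ = binary_ipd
        # x2 has missing cells; a fit of y on (x1, x2) must drop those rows
        spec = GLMMSpec(
            "binomial", "y", ("x1", "x2"), "study", ("intercept", "x1")
        )
        fit = fit_glmm(incomplete, spec, tol=1e-3)
        n_complete = (~incomplete.data[["y", "x1", "x2"]].isna().any(axis=1)).sum()
        assert fit.n_obs == n_complete
        # studies with x1 or x2 systematically missing contribute no rows
        assert set(fit.fitted_clusters) < set(incomplete.studies)

    def test_v_beta_and_omega_are_psd(self, binary_ipd):
        complete, _, _ = binary_ipd
        spec = GLMMSpec(
            "binomial", "y", ("x1", "x2"), "study", ("intercept", "x1")
        )
        fit = fit_glmm(complete, spec)
        np.linalg.cholesky(fit.V_beta + 1e-12 * np.eye(3))
        np.linalg.cholesky(fit.Omega_hat + 1e-12 * np.eye(2))
        assert set(fit.b_hat) == set(fit.fitted_clusters)
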