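import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hiermice.glmm import GLMMSpec, cluster_loglik, fit_glmm, max_cluster_loglik
from hiermice.param_draws import (
    draw_b_sporadic_ar,
    draw_b_systematic,
    draw_beta,
    draw_omega,
    draw_parameters,
)
from hiermice.synthetic import SimConfig, generate_ipd


@pytest.fixture(scope="module")
def small_fit():
    cfg = SimConfig(outcome_type="binary", n_studies=6, per_study=80, seed=9)
    ds, _ = generate_ipd(cfg)
    spec = GLMMSpec("binomial", "x1", ("x2", "y"), "study", ("intercept", "y"))
    return fit_glmm(ds, spec, tol=1e-4)


class TestDrawBeta:
    def test_zero_covariance_returns_point_estimate(self, small_fit):
        fit = small_fit
        saved = fit.V_beta
        fit.V_beta = np.zeros_like(saved)
        try:
            assert np.array_equal(
                draw_beta(fit, np.random.default_rng(0)), fit.beta_hat
            )
        finally:
            fit.V_beta = saved

    def test_moments_match_posterior(self, small_fit, rng):
        draws = np.array([draw_beta(small_fit, rng) for _ in range(10_000)])
        se = np.sqrt(np.diag(small_fit.V_beta))
        assert np.all(
            np.abs(draws.mean(axis=0) - small_fit.beta_hat)
            < 3.0 * se / np.sqrt(10_000)
        )
        emp = np.cov(draws.T)
        frob = np.linalg.norm(emp - small_fit.V_beta) / np.linalg.norm(small_fit.V_beta)
        assert frob < 0.05


class TestDrawOmega:
    def test_mean_identity_q1(self, rng):
        """Inverse-Wishart(m, S) has mean S/(m - q - 1): pins the convention."""
        m = 30
        b = rng.normal(0.0, np.sqrt(0.2), size=(m, 1))
        S = float((b.T @ b)[0, 0]) + 1e-8
        draws = np.array([draw_omega(b, rng)[0, 0] for _ in range(20_000)])
        assert draws.mean() == pytest.approx(S / (m - 1 - 1), rel=0.02)

    def test_all_draws_positive_definite(self, rng):
        b = rng.normal(size=(10, 2)) * 0.3
        for _ in range(200):
            np.linalg.cholesky(draw_omega(b, rng))

    def test_zero_modes_still_positive(self, rng):
        b = np.zeros((8, 1))
        om = draw_omega(b, rng)
        assert om[0, 0] > 0.0

    def test_too_few_studies_raises(self, rng):
        with pytest.raises(ValueError, match="q=1"):
            draw_omega(np.zeros((2, 1)), rng)


class TestDrawBSystematic:
    def test_covariance_matches_omega(self, rng):
        om = np.array([[0.4, 0.1], [0.1, 0.25]])
        draws = np.array([draw_b_systematic(om, rng) for _ in range(20_000)])
        assert np.allclose(np.cov(draws.T), om, atol=0.05 * np.max(om))

    def test_independent_across_streams(self):
        om = np.array([[0.5]])
        r1, r2 = np.random.default_rng(1), np.random.default_rng(2)
        a = np.array([draw_b_systematic(om, r1)[0] for _ in range(5_000)])
        b = np.array([draw_b_systematic(om, r2)[0] for _ in range(5_000)])
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.05


def _logistic_cluster(rng, n=50, beta=(-0.3, 0.5), b_true=0.4):
    x = rng.normal(size=n)
    eta = beta[0] + beta[1] * x + b_true
    z = rng.binomial(1, expit(eta)).astype(float)
    X = np.column_stack([np.ones(n), x])
    Z = np.ones((n, 1))
    return X, Z, z


class TestAcceptReject:
    spec = GLMMSpec("binomial", "z", ("x",), "study", ("intercept",))

    def test_bound_attained_at_maximizer(self, rng):
        """The acceptance log-ratio is 0 at b_max, so that proposal is
        accepted with probability one."""
        X, Z, z = _logistic_cluster(rng)
        beta = np.array([-0.3, 0.5])
        b_max, ll_max = max_cluster_loglik(beta, self.spec, (X, Z, z))
        assert cluster_loglik(beta, b_max, self.spec, (X, Z, z)) == pytest.approx(
            ll_max, abs=1e-9
        )

    def test_empty_cluster_rejected_by_precondition(self, rng):
        with pytest.raises(ValueError, match="systematic"):
            draw_b_sporadic_ar(
                np.zeros(2), np.array([[0.3]]), self.spec,
                (np.empty((0, 2)), np.empty((0, 1)), np.empty(0)), rng,
            )

    def test_matches_grid_posterior(self, rng):
        """Accepted draws follow phi(b; 0, Omega*) * L(b) (grid oracle)."""
        X, Z, z = _logistic_cluster(rng)
        beta = np.array([-0.3, 0.5])
        omega = np.array([[0.3]])
        draws = np.array([
            draw_b_sporadic_ar(beta, omega, self.spec, (X, Z, z), rng)[0][0]
            for _ in range(20_000)
        ])
        sig = np.sqrt(0.3)
        grid = np.linspace(-5 * sig, 5 * sig, 2001)
        eta = (X @ beta)[None, :] + grid[:, None]
        ll = np.sum(z[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
        logpost = ll - 0.5 * grid**2 / 0.3
        dens = np.exp(logpost - logpost.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(draws), grid, side="right") / len(draws)
        assert np.max(np.abs(emp - cdf)) < 0.02

    def test_acceptance_rate_matches_integrated_ratio(self, rng):
        """Mean proposals-per-acceptance ~ bound / integrated posterior."""
        X, Z, z = _logistic_cluster(rng, n=30)
        beta = np.array([-0.3, 0.5])
        omega = np.array([[0.3]])
        _, ll_max = max_cluster_loglik(beta, self.spec, (X, Z, z))
        sig = np.sqrt(0.3)
        grid = np.linspace(-6 * sig, 6 * sig, 4001)
        eta = (X @ beta)[None, :] + grid[:, None]
        ll = np.sum(z[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
        # P(accept) = E_{b~N(0,omega)}[exp(l(b) - l_max)]
        prior = np.exp(-0.5 * grid**2 / 0.3) / np.sqrt(2 * np.pi * 0.3)
        p_accept = np.trapezoid(prior * np.exp(ll - ll_max), grid)
        tries = [
            draw_b_sporadic_ar(beta, omega, self.spec, (X, Z, z), rng)[1]
            for _ in range(4_000)
        ]
        assert np.mean(tries) == pytest.approx(1.0 / p_accept, rel=0.1)


class TestDrawParameters:
    def test_identical_seed_bitwise_identical(self, small_fit):
        d1 = draw_parameters(small_fit, {"s02"}, np.random.default_rng(42))
        d2 = draw_parameters(small_fit, {"s02"}, np.random.default_rng(42))
        assert np.array_equal(d1.beta_star, d2.beta_star)
        assert np.array_equal(d1.omega_star, d2.omega_star)
        for k in d1.b_star:
            assert np.array_equal(d1.b_star[k], d2.b_star[k])

    def test_covers_every_study(self, small_fit):
        d = draw_parameters(small_fit, {"s02"}, np.random.default_rng(1))
        assert set(d.b_star) == set(small_fit.fitted_clusters) | {"s02"}
        np.linalg.cholesky(d.omega_star)
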