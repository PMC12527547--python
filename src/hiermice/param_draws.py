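"""Posterior parameter draws for one multilevel imputation.

Each imputation needs one draw of (beta*, Omega*, {b*_i}).  Fixed effects
are drawn from the approximate normal posterior N(beta_hat, V_beta); the
random-effects covariance from an inverse-Wishart whose scale is the outer
product sum of the conditional modes of the contributing studies; and the
study-level random effects either from their prior N(0, Omega*) (studies
where the variable is systematically missing) or, where the variable is
partially observed, from the exact conditional posterior via accept-reject
sampling with the prior as proposal and the per-cluster likelihood at its
maximizer as the bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .glmm import GLMMFit, GLMMSpec, _mu, _pd_inv, _weights, cluster_loglik, max_cluster_loglik

__all__ = [
    "ParameterDraw",
    "draw_beta",
    "draw_omega",
    "draw_b_systematic",
    "draw_b_sporadic_ar",
    "draw_parameters",
]

logger = logging.getLogger("hiermice")


@dataclass
class ParameterDraw:
    """One joint posterior draw used to generate one imputation."""

    beta_star: np.ndarray
    omega_star: np.ndarray
    b_star: dict[str, np.ndarray]
    sigma2_star: float | None = None
    ar_stats: dict[str, tuple[int, int]] = field(default_factory=dict)


def _psd_cholesky(V: np.ndarray, clip: float = 1e-10) -> np.ndarray:
    """Cholesky factor after flooring eigenvalues at ``clip`` (PSD guard)."""
    V = 0.5 * (np.asarray(V, float) + np.asarray(V, float).T)
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(V)
        if np.min(vals) < -1e-6 * max(1.0, np.max(np.abs(vals))):
            raise FloatingPointError("covariance matrix is not PSD after clipping")
        vals = np.clip(vals, clip, None)
        return np.linalg.cholesky((vecs * vals) @ vecs.T)


def draw_beta(fit: GLMMFit, rng: np.random.Generator) -> np.ndarray:
    """beta* ~ N(beta_hat, V_beta)."""
    V = fit.V_beta
    if np.allclose(V, 0.0):
        return fit.beta_hat.copy()
    L = _psd_cholesky(V)
    return fit.beta_hat + L @ rng.standard_normal(len(fit.beta_hat))


def draw_omega(
    b_hats: list[np.ndarray] | np.ndarray,
    rng: np.random.Generator,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Omega* ~ Inverse-Wishart(m, S), S = sum_i b_hat_i b_hat_i' + ridge*I.

    ``m`` is the number of contributing studies (those observing the
    variable at least partially); systematically missing studies do not
    contribute.  The small ridge guards nearly collinear conditional modes.
    Requires m >= q + 2 so that the draw has a finite mean S/(m - q - 1).
    """
    B = np.atleast_2d(np.asarray(b_hats, dtype=float))
    m, q = B.shape
    if m < q + 2:
        raise ValueError(
            f"only {m} contributing studies for q={q} random effects; need "
            f"m >= {q + 2}. Consider a random-intercept-only model (q=1)."
        )
    S = B.T @ B + ridge * np.eye(q)
    draw = invwishart.rvs(df=m, scale=S, random_state=rng)
    return np.atleast_2d(draw)


def draw_b_systematic(omega_star: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """b* ~ N(0, Omega*) — the unconditional (prior) draw."""
    L = _psd_cholesky(omega_star)
    return L @ rng.standard_normal(omega_star.shape[0])


def draw_b_sporadic_ar(
    beta_star: np.ndarray,
    omega_star: np.ndarray,
    spec: GLMMSpec,
    cluster_rows: pd.DataFrame | tuple,
    rng: np.random.Generator,
    max_tries: int = 10_000,
    sigma2: float = 1.0,
    study_label: str = "?",
) -> tuple[np.ndarray, int]:
    """Accept-reject draw from the conditional posterior of one study's b.

    Proposes b' ~ N(0, Omega*) and accepts with probability
    exp(l(b') - l_max), where l is the cluster log-likelihood at beta* and
    l_max its maximum over b; the comparison is done entirely in the log
    domain.  Returns the accepted draw and the number of proposals tried.

    If ``max_tries`` proposals are exhausted (very informative clusters with
    a prior-dominated proposal), falls back to a Laplace-approximate draw
    N(b_mode, (-H(b_mode) + Omega*^-1)^-1) of the same posterior and logs a
    warning naming the study.
    """
    from .glmm import build_design

    X, Z, z = (
        cluster_rows
        if isinstance(cluster_rows, tuple)
        else build_design(cluster_rows, spec)
    )
    if len(z) == 0:
        raise ValueError(
            "accept-reject branch requires >= 1 observed row; route "
            "systematically missing studies to draw_b_systematic"
        )
    q = omega_star.shape[0]
    _, ll_max = max_cluster_loglik(beta_star, spec, (X, Z, z), sigma2=sigma2)
    L = _psd_cholesky(omega_star)
    offset = X @ np.asarray(beta_star, float)

    # vectorized batches of proposals; acceptance test in the log domain
    batch = 64
    tries = 0
    while tries < max_tries:
        nprop = min(batch, max_tries - tries)
        props = rng.standard_normal((nprop, q)) @ L.T
        log_u = np.log(rng.uniform(size=nprop))
        etas = offset[None, :] + props @ Z.T
        lls = _batch_loglik(spec.family, z, etas, sigma2)
        accept = log_u <= lls - ll_max
        idx = np.argmax(accept)
        if accept[idx]:
            tries += int(idx) + 1
            return props[idx], tries
        tries += nprop
        batch = min(batch * 2, 4096)

    # exhaustion fallback: Laplace approximation of the same posterior
    logger.warning(
        "accept-reject exhausted %d proposals for study %s; "
        "using Laplace-approximate draw", max_tries, study_label,
    )
    b_mode, V_post = _laplace_posterior(beta_star, omega_star, spec, (X, Z, z), sigma2)
    Lp = _psd_cholesky(V_post)
    return b_mode + Lp @ rng.standard_normal(q), max_tries


def _batch_loglik(family: str, z: np.ndarray, etas: np.ndarray, sigma2: float):
    """Row-wise log-likelihood for a batch of linear predictors."""
    if family == "gaussian":
        return (
            -0.5 * np.sum((z[None, :] - etas) ** 2, axis=1) / sigma2
            - 0.5 * len(z) * np.log(2 * np.pi * sigma2)
        )
    if family == "binomial":
        return np.sum(z[None, :] * etas - np.logaddexp(0.0, etas), axis=1)
    from scipy.special import gammaln

    mu = np.exp(np.clip(etas, -500, 30))
    return np.sum(z[None, :] * etas - mu - gammaln(z + 1.0)[None, :], axis=1)


def _laplace_posterior(beta_star, omega_star, spec, design, sigma2):
    """Mode and curvature-based covariance of the b-posterior of one study."""
    X, Z, z = design
    omega_inv = _pd_inv(omega_star)
    offset = X @ np.asarray(beta_star, float)
    q = omega_star.shape[0]
    b = np.zeros(q)
    for _ in range(100):
        eta = offset + Z @ b
        mu = _mu(spec.family, eta)
        w = _weights(spec.family, mu, sigma2)
        r = (z - mu) / sigma2 if spec.family == "gaussian" else z - mu
        grad = Z.T @ r - omega_inv @ b
        H = (Z * w[:, None]).T @ Z + omega_inv
        step = np.linalg.solve(H, grad)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = offset + Z @ b
    w = _weights(spec.family, _mu(spec.family, eta), sigma2)
    V = _pd_inv((Z * w[:, None]).T @ Z + omega_inv)
    return b, V


def draw_parameters(
    fit: GLMMFit,
    systematic_studies: set[str],
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> ParameterDraw:
    """Draw (beta*, Omega*, {b*_i}) for every study in one pass.

    Studies in ``systematic_studies`` get prior draws; studies with observed
    data get accept-reject draws conditioned on their rows.  For the
    Gaussian family the residual variance is drawn as sigma2_hat * df /
    chi2_df with df = n_obs - p, and the sporadic branch still uses the
    (exact, since the posterior is Gaussian) accept-reject path unless the
    caller substitutes the closed form.
    """
    beta_star = draw_beta(fit, rng)
    b_hats = [fit.b_hat[c] for c in fit.fitted_clusters]
    omega_star = draw_omega(b_hats, rng)
    sigma2_star = None
    sigma2 = 1.0
    if fit.spec.family == "gaussian":
        df = max(fit.n_obs - fit.spec.p, 1)
        sigma2_star = float(fit.sigma2_hat * df / rng.chisquare(df))
        sigma2 = sigma2_star

    b_star: dict[str, np.ndarray] = {}
    ar_stats: dict[str, tuple[int, int]] = {}
    for study in sorted(systematic_studies):  # sorted: run-to-run determinism
        b_star[study] = draw_b_systematic(omega_star, rng)
    for study in fit.fitted_clusters:
        if study in systematic_studies:
            continue
        design = fit.cluster_data[study]
        b, tries = draw_b_sporadic_ar(
            beta_star, omega_star, fit.spec, design, rng,
            max_tries=max_tries, sigma2=sigma2, study_label=study,
        )
        b_star[study] = b
        ar_stats[study] = (tries, 1)
    return ParameterDraw(beta_star, omega_star, b_star, sigma2_star, ar_stats)
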