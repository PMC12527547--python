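"""Generalized linear mixed models with study-level random effects.

Supports the three conditional families used by the imputation machinery —
Gaussian (identity link), binomial (logit) and Poisson (log) — with a
random intercept plus optional random slopes, two levels only (participant
within study).

Fitting maximizes the Laplace-approximate marginal likelihood by
alternating a penalized-IRLS joint Newton solve for (beta, b_1..b_m) with
an EM-type update of the random-effects covariance Omega (and, for the
Gaussian family, the residual variance).  For the Gaussian family this is
the exact EM algorithm for maximum likelihood.  The fixed-effects
covariance V_beta is the inverse observed information of beta after
profiling out the random effects at their conditional modes (the Schur
complement of the joint Hessian), conditional on the estimated Omega.

The module also exposes the per-cluster log-likelihood in b and its
maximizer, the two ingredients of the accept-reject random-effects sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .data_model import IPDataset

__all__ = [
    "GLMMSpec",
    "GLMMFit",
    "fit_glmm",
    "cluster_loglik",
    "max_cluster_loglik",
    "EstimationError",
]

FAMILIES = ("gaussian", "binomial", "poisson")
INTERCEPT = "intercept"


class EstimationError(RuntimeError):
    """The mixed model cannot be estimated on the supplied data."""


@dataclass(frozen=True)
class GLMMSpec:
    """Specification of one generalized linear mixed model.

    ``fixed_predictors`` are column names; an intercept is always included
    first.  ``random_design`` lists the q columns of the random-effects
    design (the literal name ``"intercept"`` plus any fixed predictor).
    """

    family: str
    response: str
    fixed_predictors: tuple[str, ...]
    cluster: str
    random_design: tuple[str, ...] = (INTERCEPT,)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.random_design) < 1:
            raise ValueError("random_design must have q >= 1 columns")
        allowed = {INTERCEPT, *self.fixed_predictors}
        bad = [v for v in self.random_design if v not in allowed]
        if bad:
            raise ValueError(f"random_design terms {bad} not among predictors")

    @property
    def q(self) -> int:
        return len(self.random_design)

    @property
    def p(self) -> int:
        return len(self.fixed_predictors) + 1


@dataclass
class GLMMFit:
    """Fitted state of a GLMM: point estimates and conditional modes."""

    spec: GLMMSpec
    beta_hat: np.ndarray
    V_beta: np.ndarray
    b_hat: dict[str, np.ndarray]
    Omega_hat: np.ndarray
    sigma2_hat: float | None
    loglik: float
    converged: bool
    fitted_clusters: list[str]
    n_obs: int
    # per-cluster observed designs (X, Z, z), kept for the samplers
    cluster_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        repr=False, default_factory=dict
    )


# ---------------------------------------------------------------------------
# family helpers (canonical links)
# ---------------------------------------------------------------------------

def _mu(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "gaussian":
        return eta
    if family == "binomial":
        return expit(eta)
    return np.exp(np.clip(eta, -500, 30))


def _weights(family: str, mu: np.ndarray, sigma2: float) -> np.ndarray:
    if family == "gaussian":
        return np.full_like(mu, 1.0 / sigma2)
    if family == "binomial":
        return np.clip(mu * (1.0 - mu), 1e-10, None)
    return np.clip(mu, 1e-10, None)


def _loglik_terms(family: str, z: np.ndarray, eta: np.ndarray, sigma2: float) -> float:
    if family == "gaussian":
        return float(
            -0.5 * np.sum((z - eta) ** 2) / sigma2
            - 0.5 * len(z) * np.log(2.0 * np.pi * sigma2)
        )
    if family == "binomial":
        # z*eta - log(1+exp(eta)), computed stably
        return float(np.sum(z * eta - np.logaddexp(0.0, eta)))
    mu = np.exp(np.clip(eta, -500, 30))
    return float(np.sum(z * eta - mu - gammaln(z + 1.0)))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    rows: pd.DataFrame, spec: GLMMSpec, require_response: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (X, Z, z) for the given rows; rows must be complete."""
    n = len(rows)
    X = np.ones((n, spec.p))
    for j, name in enumerate(spec.fixed_predictors, start=1):
        X[:, j] = rows[name].to_numpy(dtype=float)
    Z = np.ones((n, spec.q))
    for j, name in enumerate(spec.random_design):
        if name != INTERCEPT:
            Z[:, j] = rows[name].to_numpy(dtype=float)
    if require_response:
        z = rows[spec.response].to_numpy(dtype=float)
    else:
        z = np.full(n, np.nan)
    return X, Z, z


def _complete_cluster_designs(
    ds: IPDataset, spec: GLMMSpec
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-cluster (X, Z, z) over rows with response and predictors observed."""
    cols = [spec.response, *spec.fixed_predictors]
    ok = ~ds.data[cols].isna().any(axis=1)
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for study, rows in ds.data.loc[ok].groupby(ds.cluster_col, sort=False):
        out[study] = build_design(rows, spec)
    return out


# ---------------------------------------------------------------------------
# per-cluster likelihood in b
# ---------------------------------------------------------------------------

def cluster_loglik(
    beta: np.ndarray,
    b: np.ndarray,
    spec: GLMMSpec,
    cluster_rows: pd.DataFrame | tuple,
    sigma2: float = 1.0,
) -> float:
    """Log-likelihood of one study's observed rows at fixed (beta, b).

    ``cluster_rows`` may be a DataFrame of fully observed rows or a
    prebuilt ``(X, Z, z)`` design triple.  Empty input returns 0.0.
    """
    X, Z, z = (
        cluster_rows
        if isinstance(cluster_rows, tuple)
        else build_design(cluster_rows, spec)
    )
    if len(z) == 0:
        return 0.0
    b = np.asarray(b, dtype=float).ravel()
    if b.shape[0] != Z.shape[1]:
        raise ValueError(
            f"random-effect vector has length {b.shape[0]}, design has q={Z.shape[1]}"
        )
    eta = X @ np.asarray(beta, dtype=float) + Z @ b
    return _loglik_terms(spec.family, z, eta, sigma2)


def max_cluster_loglik(
    beta: np.ndarray,
    spec: GLMMSpec,
    cluster_rows: pd.DataFrame | tuple,
    sigma2: float = 1.0,
    b_max_box: float = 20.0,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Maximize the per-cluster log-likelihood over b (damped Newton).

    The likelihood is log-concave in b for all three families, so the
    maximizer is unique whenever the cluster design has full column rank
    and the responses are non-degenerate.  Under separation the search is
    capped at ``|b|_inf <= b_max_box`` and a warning is emitted.
    """
    X, Z, z = (
        cluster_rows
        if isinstance(cluster_rows, tuple)
        else build_design(cluster_rows, spec)
    )
    q = Z.shape[1]
    if len(z) == 0:
        return np.zeros(q), 0.0
    beta = np.asarray(beta, dtype=float)
    offset = X @ beta
    b = np.zeros(q)
    ll = _loglik_terms(spec.family, z, offset, sigma2)
    capped = False
    for _ in range(max_iter):
        eta = offset + Z @ b
        mu = _mu(spec.family, eta)
        w = _weights(spec.family, mu, sigma2)
        resid = (z - mu) / sigma2 if spec.family == "gaussian" else z - mu
        grad = Z.T @ resid
        H = (Z * w[:, None]).T @ Z + 1e-12 * np.eye(q)
        step = np.linalg.solve(H, grad)
        # backtracking on the concave objective
        t = 1.0
        for _ in range(40):
            b_new = np.clip(b + t * step, -b_max_box, b_max_box)
            ll_new = _loglik_terms(spec.family, z, offset + Z @ b_new, sigma2)
            if ll_new >= ll - 1e-14:
                break
            t *= 0.5
        moved = np.max(np.abs(b_new - b))
        b, ll = b_new, ll_new
        if np.any(np.abs(b) >= b_max_box - 1e-9):
            capped = True
        if moved < tol:
            break
    if capped:
        warnings.warn(
            "per-cluster likelihood maximizer hit the |b| box bound "
            f"({b_max_box}); possible separation", RuntimeWarning,
        )
    return b, ll


# ---------------------------------------------------------------------------
# full model fit
# ---------------------------------------------------------------------------

def fit_glmm(
    ds: IPDataset,
    spec: GLMMSpec,
    max_outer: int = 200,
    tol: float = 1e-5,
    allow_fallback: bool = True,
) -> GLMMFit:
    """Fit the GLMM on all rows with observed response and predictors.

    Clusters contributing zero observed response rows are absent from
    ``fitted_clusters`` (and from the Omega scale matrix downstream).  On
    non-convergence the model is refit with a random intercept only and
    flagged ``converged=False`` if that also fails.
    """
    cdata = _complete_cluster_designs(ds, spec)
    cdata = {k: v for k, v in cdata.items() if len(v[2]) > 0}
    if len(cdata) < 2:
        raise EstimationError(
            f"response {spec.response!r} observed in {len(cdata)} cluster(s); "
            "need at least 2"
        )
    Xall = np.vstack([v[0] for v in cdata.values()])
    if np.linalg.matrix_rank(Xall) < spec.p:
        raise EstimationError("fixed-effects design is rank deficient on observed rows")

    fit = _laplace_em(cdata, spec, max_outer=max_outer, tol=tol)
    if fit is None or not fit.converged:
        if allow_fallback and spec.q > 1:
            simple = GLMMSpec(
                spec.family, spec.response, spec.fixed_predictors,
                spec.cluster, (INTERCEPT,),
            )
            warnings.warn(
                f"GLMM for {spec.response!r} did not converge; refitting with "
                "a random intercept only", RuntimeWarning,
            )
            sdata = {k: (X, Z[:, :1], z) for k, (X, Z, z) in cdata.items()}
            sfit = _laplace_em(sdata, simple, max_outer=max_outer, tol=tol)
            if sfit is not None:
                # embed the q=1 result in the original q-dim parameterization
                q = spec.q
                Omega = np.full((q, q), 1e-10)
                Omega[0, 0] = sfit.Omega_hat[0, 0]
                b_hat = {
                    k: np.concatenate([v, np.zeros(q - 1)])
                    for k, v in sfit.b_hat.items()
                }
                return GLMMFit(
                    spec, sfit.beta_hat, sfit.V_beta, b_hat, Omega,
                    sfit.sigma2_hat, sfit.loglik, False,
                    sfit.fitted_clusters, sfit.n_obs, cdata,
                )
        if fit is None:
            raise EstimationError(f"GLMM fit failed for {spec.response!r}")
    return fit


class _Packed:
    """Cluster-sorted concatenated designs with segment boundaries.

    Lets every per-cluster quantity (gradients, information blocks,
    conditional covariances) be computed by one ``reduceat``/batched-solve
    pass instead of a Python loop over studies.
    """

    def __init__(self, cdata: dict):
        self.clusters = list(cdata)
        self.X = np.vstack([cdata[c][0] for c in self.clusters])
        self.Z = np.vstack([cdata[c][1] for c in self.clusters])
        self.z = np.concatenate([cdata[c][2] for c in self.clusters])
        sizes = [len(cdata[c][2]) for c in self.clusters]
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
        self.m = len(self.clusters)
        self.N = len(self.z)
        # row-wise outer-product templates reused each Newton step
        self.XX = self.X[:, :, None] * self.X[:, None, :]
        self.XZ = self.X[:, :, None] * self.Z[:, None, :]
        self.ZZ = self.Z[:, :, None] * self.Z[:, None, :]
        self.row = np.repeat(np.arange(self.m),
                             np.diff(np.concatenate([self.starts, [self.N]])))

    def seg(self, arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr, self.starts, axis=0)


def _eta(pack: _Packed, beta, bs) -> np.ndarray:
    return pack.X @ beta + np.einsum("nq,nq->n", pack.Z, bs[pack.row])


def _penalized_obj(pack, beta, bs, Omega_inv, family, sigma2) -> float:
    ll = _loglik_terms(family, pack.z, _eta(pack, beta, bs), sigma2)
    return ll - 0.5 * float(np.einsum("iq,qr,ir->", bs, Omega_inv, bs))


def _pirls(pack: _Packed, beta, bs, Omega_inv, family, sigma2,
           n_steps: int = 30, tol: float = 1e-9):
    """Joint Newton maximization of the penalized log-likelihood over
    (beta, b_1..b_m) at fixed Omega, via block elimination of the b-blocks
    (Schur complement on beta), with step halving."""
    p, q = pack.X.shape[1], pack.Z.shape[1]
    obj = _penalized_obj(pack, beta, bs, Omega_inv, family, sigma2)
    for _ in range(n_steps):
        eta = _eta(pack, beta, bs)
        mu = _mu(family, eta)
        w = _weights(family, mu, sigma2)
        r = (pack.z - mu) / sigma2 if family == "gaussian" else pack.z - mu
        A = np.einsum("n,npr->pr", w, pack.XX)
        B = pack.seg(w[:, None, None] * pack.XZ)                 # (m, p, q)
        D = pack.seg(w[:, None, None] * pack.ZZ) + Omega_inv     # (m, q, q)
        g_beta = pack.X.T @ r
        g_b = pack.seg(pack.Z * r[:, None]) - bs @ Omega_inv     # (m, q)
        Dinv_g = np.linalg.solve(D, g_b[:, :, None])[:, :, 0]
        Dinv_Bt = np.linalg.solve(D, np.transpose(B, (0, 2, 1)))
        M = A - np.einsum("ipq,iqr->pr", B, Dinv_Bt) + 1e-10 * np.eye(p)
        try:
            d_beta = np.linalg.solve(M, g_beta - np.einsum("ipq,iq->p", B, Dinv_g))
        except np.linalg.LinAlgError:
            return beta, bs, False
        if not np.all(np.isfinite(d_beta)):
            return beta, bs, False
        d_bs = np.linalg.solve(
            D, (g_b - np.einsum("ipq,p->iq", B, d_beta))[:, :, None]
        )[:, :, 0]
        t = 1.0
        for _ in range(40):
            beta_new = beta + t * d_beta
            bs_new = bs + t * d_bs
            obj_new = _penalized_obj(pack, beta_new, bs_new, Omega_inv, family, sigma2)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            t *= 0.5
        step_size = max(np.max(np.abs(t * d_beta)), np.max(np.abs(t * d_bs)))
        beta, bs, obj = beta_new, bs_new, obj_new
        if step_size < tol:
            break
    return beta, bs, True


def _estep(pack, beta, bs, Omega_inv, family, sigma2):
    """Conditional covariances V_i and the EM updates of (Omega, sigma2)."""
    eta = _eta(pack, beta, bs)
    mu = _mu(family, eta)
    w = _weights(family, mu, sigma2)
    D = pack.seg(w[:, None, None] * pack.ZZ) + Omega_inv
    V = np.linalg.inv(D)                                         # (m, q, q)
    Omega_new = (np.einsum("iq,ir->qr", bs, bs) + V.sum(axis=0)) / pack.m
    sigma2_new = None
    if family == "gaussian":
        rss = float(np.sum((pack.z - eta) ** 2))
        tr = float(np.einsum("npq,nqp->", pack.ZZ, V[pack.row]))
        sigma2_new = (rss + tr) / pack.N
    return 0.5 * (Omega_new + Omega_new.T), sigma2_new, V


def _chol_pack(Omega: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Omega + 1e-12 * np.eye(Omega.shape[0]))
    return L[np.tril_indices_from(L)]

def _chol_unpack(v: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = v
    return L @ L.T


def _laplace_em(cdata, spec: GLMMSpec, max_outer: int, tol: float) -> GLMMFit | None:
    """SQUAREM-accelerated EM on (Omega[, sigma2]) around the PIRLS core.

    The EM fixed-point map is run in Cholesky coordinates of Omega (log
    coordinates for sigma2) so the squared-extrapolation steps stay inside
    the positive-definite cone.
    """
    family, q, p = spec.family, spec.q, spec.p
    pack = _Packed(cdata)

    beta = _glm_irls(pack.X, pack.z, family)
    if beta is None:
        return None
    state = {"beta": beta, "bs": np.zeros((pack.m, q))}
    sigma2_0 = (
        float(np.var(pack.z - pack.X @ beta) + 1e-8) if family == "gaussian" else 1.0
    )

    def em_map(theta: np.ndarray) -> np.ndarray | None:
        Omega = _chol_unpack(theta[: q * (q + 1) // 2], q)
        sigma2 = float(np.exp(theta[-1])) if family == "gaussian" else 1.0
        Omega_inv = _pd_inv(Omega)
        beta, bs, ok = _pirls(
            pack, state["beta"], state["bs"], Omega_inv, family, sigma2, n_steps=8
        )
        if not ok:
            return None
        state["beta"], state["bs"] = beta, bs
        Omega_new, sigma2_new, _ = _estep(pack, beta, bs, Omega_inv, family, sigma2)
        out = _chol_pack(Omega_new)
        if family == "gaussian":
            out = np.append(out, np.log(max(sigma2_new, 1e-12)))
        return out

    theta = _chol_pack(0.1 * np.eye(q))
    if family == "gaussian":
        theta = np.append(theta, np.log(sigma2_0))

    converged = False
    n_cycles = max(max_outer // 3, 10)
    for _ in range(n_cycles):
        t1 = em_map(theta)
        if t1 is None:
            return None
        t2 = em_map(t1)
        if t2 is None:
            return None
        r = t1 - theta
        v = (t2 - t1) - r
        scale = np.max(np.abs(t2)) + 1e-12
        if np.max(np.abs(t2 - t1)) < tol * scale:
            theta = t2
            converged = True
            break
        nv = np.linalg.norm(v)
        if nv < 1e-14:
            theta = t2
            converged = True
            break
        alpha = -max(np.linalg.norm(r) / nv, 1.0)
        t_acc = theta - 2.0 * alpha * r + alpha**2 * v
        t3 = em_map(t_acc) if np.all(np.isfinite(t_acc)) else None
        theta = t3 if t3 is not None else t2

    Omega = _chol_unpack(theta[: q * (q + 1) // 2], q)
    sigma2 = float(np.exp(theta[-1])) if family == "gaussian" else 1.0
    Omega_inv = _pd_inv(Omega)

    # final conditional-mode refresh, covariance, and Laplace log-likelihood
    beta, bs, ok = _pirls(
        pack, state["beta"], state["bs"], Omega_inv, family, sigma2, n_steps=50
    )
    if not ok:
        return None
    eta = _eta(pack, beta, bs)
    mu = _mu(family, eta)
    w = _weights(family, mu, sigma2)
    A = np.einsum("n,npr->pr", w, pack.XX)
    B = pack.seg(w[:, None, None] * pack.XZ)
    ZWZ = pack.seg(w[:, None, None] * pack.ZZ)
    D = ZWZ + Omega_inv
    Dinv_Bt = np.linalg.solve(D, np.transpose(B, (0, 2, 1)))
    V_beta = _pd_inv(A - np.einsum("ipq,iqr->pr", B, Dinv_Bt))
    ll = _loglik_terms(family, pack.z, eta, sigma2)
    ll -= 0.5 * float(np.einsum("iq,qr,ir->", bs, Omega_inv, bs))
    sign, logdet = np.linalg.slogdet(np.eye(q)[None] + Omega[None] @ ZWZ)
    ll -= 0.5 * float(np.sum(logdet))

    return GLMMFit(
        spec=spec,
        beta_hat=beta,
        V_beta=V_beta,
        b_hat={c: bs[i].copy() for i, c in enumerate(pack.clusters)},
        Omega_hat=Omega,
        sigma2_hat=sigma2 if family == "gaussian" else None,
        loglik=ll,
        converged=converged,
        fitted_clusters=pack.clusters,
        n_obs=pack.N,
        cluster_data=dict(cdata),
    )


def _glm_irls(X, z, family, max_iter=100, tol=1e-10):
    """Plain GLM IRLS used only for initialization."""
    n, p = X.shape
    beta = np.zeros(p)
    if family == "gaussian":
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        return beta
    mean = np.clip(np.mean(z), 1e-3, None)
    if family == "binomial":
        mean = np.clip(mean, 1e-3, 1 - 1e-3)
        beta[0] = np.log(mean / (1 - mean))
    else:
        beta[0] = np.log(mean)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _mu(family, eta)
        w = _weights(family, mu, 1.0)
        grad = X.T @ (z - mu)
        H = (X * w[:, None]).T @ X + 1e-8 * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return None
        beta = beta + np.clip(step, -5, 5)
        if np.max(np.abs(step)) < tol:
            break
    return beta if np.all(np.isfinite(beta)) else None


def _pd_inv(M: np.ndarray) -> np.ndarray:
    """Inverse of a (nearly) PD symmetric matrix with an eigenvalue floor."""
    M = np.asarray(M, dtype=float)
    M = 0.5 * (M + M.T)
    try:
        L = np.linalg.cholesky(M)
        Linv = np.linalg.inv(L)
        return Linv.T @ Linv
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(M)
        vals = np.clip(vals, 1e-10, None)
        return (vecs / vals) @ vecs.T
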