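"""Benchmark imputation strategies: stratified (STI), two-stage (2STG), CCA.

STI ignores the hierarchical structure during modelling and instead adds
fixed study-indicator dummies to a single-level imputation model (Bayesian
logistic imputation for binary targets, predictive mean matching for
counts); studies where the target is systematically missing borrow the
arithmetic mean of the observed studies' intercepts.  2STG fits the
imputation model separately per study and combines the coefficients by a
method-of-moments multivariate random-effects meta-analysis; study-specific
imputation coefficients are then drawn from the conditional posterior
(observed studies) or the predictive distribution (systematic studies),
which treats sporadically missing cells the same way as systematic ones at
the draw level.  CCA simply deletes incomplete rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import IPDataset, classify_missingness
from .glmm import _mu, _pd_inv, _weights
from .imputers import ImputationError, _sample_family
from .param_draws import _psd_cholesky

__all__ = ["TwoStageFit", "impute_sti", "impute_2stg", "cca_filter",
           "fill_systematic_intercepts", "pmm_match"]

FAMILY_FOR_VTYPE = {"binary": "binomial", "count": "poisson", "continuous": "gaussian"}


def _require_complete_predictors(ds: IPDataset, predictors) -> None:
    for p in predictors:
        if ds.data[p].isna().any():
            raise ImputationError(
                f"predictor {p!r} has missing entries; the engine must supply "
                "a current fill"
            )


# ---------------------------------------------------------------------------
# STI — stratified imputation with fixed study dummies
# ---------------------------------------------------------------------------

def fill_systematic_intercepts(
    intercepts: dict[str, float], systematic: list[str]
) -> dict[str, float]:
    """Assign each systematic study the mean of the observed intercepts."""
    mean = float(np.mean(list(intercepts.values())))
    out = dict(intercepts)
    for s in systematic:
        out[s] = mean
    return out


def _sti_design(ds: IPDataset, rows: pd.DataFrame, studies: list[str],
                predictors: tuple[str, ...]) -> np.ndarray:
    """One-hot study dummies (no global intercept) followed by predictors."""
    n = len(rows)
    X = np.zeros((n, len(studies) + len(predictors)))
    labels = rows[ds.cluster_col].to_numpy()
    for j, s in enumerate(studies):
        X[:, j] = labels == s
    for j, p in enumerate(predictors, start=len(studies)):
        X[:, j] = rows[p].to_numpy(dtype=float)
    return X


def _glm_fit_ridge(X, z, family, ridge=0.0, max_iter=200):
    """IRLS with optional ridge; returns (beta, cov) or None."""
    p = X.shape[1]
    beta = np.zeros(p)
    if family == "gaussian" and ridge == 0.0:
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    for _ in range(max_iter if family != "gaussian" or ridge > 0 else 0):
        eta = X @ beta
        mu = _mu(family, eta)
        w = _weights(family, mu, 1.0)
        grad = X.T @ (z - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return None
        beta = beta + np.clip(step, -10, 10)
        if not np.all(np.isfinite(beta)):
            return None
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = X @ beta
    w = _weights(family, _mu(family, eta), 1.0)
    H = (X * w[:, None]).T @ X + ridge * np.eye(p)
    try:
        cov = _pd_inv(H)
    except np.linalg.LinAlgError:
        return None
    return beta, cov


def impute_sti(
    ds: IPDataset,
    target: str,
    predictors: tuple[str, ...] | list[str],
    rng: np.random.Generator,
) -> pd.Series:
    """Stratified imputation of one variable (fixed dummies, no random effects).

    Binary targets: Bayesian logistic-regression imputation (coefficients
    drawn from the asymptotic normal posterior, cells sampled Bernoulli).
    Count (or continuous) targets: type-1 predictive mean matching with a
    k=5 donor pool.  Separation is handled by a ridge-stabilized refit.
    """
    predictors = tuple(predictors)
    vtype = ds.var_spec(target).vtype
    _require_complete_predictors(ds, predictors)
    pattern = classify_missingness(ds, target)
    observing = [s for s in ds.studies
                 if pattern.per_study_status[s] != "systematic"]
    systematic = pattern.studies_with("systematic")
    if not observing:
        raise ImputationError(f"{target!r} observed in no study")

    col = ds.data[target].copy()
    miss = col.isna()
    if not miss.any():
        return col
    obs_rows = ds.data.loc[~miss]
    n_studies_obs = len(observing)

    family = "binomial" if vtype == "binary" else "gaussian"
    Xo = _sti_design(ds, obs_rows, observing, predictors)
    zo = obs_rows[target].to_numpy(dtype=float)
    fitted = _glm_fit_ridge(Xo, zo, family)
    if fitted is None or not np.all(np.isfinite(fitted[0])):
        fitted = _glm_fit_ridge(Xo, zo, family, ridge=1e-4)
        warnings.warn(
            f"STI fit for {target!r} was singular/separated; "
            "ridge-stabilized (lambda=1e-4)", RuntimeWarning,
        )
    beta_hat, cov = fitted
    if family == "binomial" and np.max(np.abs(beta_hat[:n_studies_obs])) > 15:
        # perfectly separated study dummy: refit with ridge
        warnings.warn(
            f"STI study dummy separated for {target!r}; "
            "ridge-stabilized (lambda=1e-4)", RuntimeWarning,
        )
        beta_hat, cov = _glm_fit_ridge(Xo, zo, family, ridge=1e-4)

    if family == "gaussian":
        df = max(len(zo) - Xo.shape[1], 1)
        sigma2_hat = float(np.sum((zo - Xo @ beta_hat) ** 2) / df)
        sigma2_star = sigma2_hat * df / rng.chisquare(df)
        beta_star = beta_hat + _psd_cholesky(cov * sigma2_star) @ \
            rng.standard_normal(len(beta_hat))
    else:
        beta_star = beta_hat + _psd_cholesky(cov) @ rng.standard_normal(len(beta_hat))

    # extend the coefficient vectors with systematic-study intercepts
    all_studies = observing + systematic
    def extend(b):
        icpt = fill_systematic_intercepts(
            dict(zip(observing, b[:n_studies_obs])), systematic
        )
        return np.concatenate([[icpt[s] for s in all_studies], b[n_studies_obs:]])

    beta_hat_x = extend(beta_hat)
    beta_star_x = extend(beta_star)

    miss_rows = ds.data.loc[miss]
    Xm = _sti_design(ds, miss_rows, all_studies, predictors)
    if vtype == "binary":
        eta = Xm @ beta_star_x
        col.loc[miss_rows.index] = rng.binomial(1, expit(eta)).astype(float)
    else:
        Xo_x = _sti_design(ds, obs_rows, all_studies, predictors)
        donor_pred = Xo_x @ beta_hat_x   # type-1: donors at the point estimate
        miss_pred = Xm @ beta_star_x     # recipients at the drawn coefficients
        imputed = pmm_match(miss_pred, donor_pred, zo, rng, k=5)
        col.loc[miss_rows.index] = imputed
    return col


def pmm_match(
    miss_pred: np.ndarray,
    donor_pred: np.ndarray,
    donor_values: np.ndarray,
    rng: np.random.Generator,
    k: int = 5,
) -> np.ndarray:
    """Predictive mean matching: for each recipient pick uniformly among the
    k donors whose predicted mean is closest, and impute that donor's
    observed value."""
    k = min(k, len(donor_pred))
    order = np.argsort(donor_pred, kind="stable")
    sorted_pred = donor_pred[order]
    out = np.empty(len(miss_pred))
    for i, mp in enumerate(miss_pred):
        # k nearest by |predicted mean difference| via the sorted donor list
        pos = np.searchsorted(sorted_pred, mp)
        lo = max(0, pos - k)
        hi = min(len(sorted_pred), pos + k)
        window = order[lo:hi]
        d = np.abs(donor_pred[window] - mp)
        nearest = window[np.argsort(d, kind="stable")[:k]]
        out[i] = donor_values[nearest[rng.integers(len(nearest))]]
    return out


# ---------------------------------------------------------------------------
# 2STG — per-study fits combined by random-effects meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class TwoStageFit:
    """Stage-1 per-study coefficients and the stage-2 meta-analysis."""

    per_study_coef: dict[str, tuple[np.ndarray, np.ndarray]]
    pooled_coef: np.ndarray
    pooled_cov: np.ndarray
    between_cov: np.ndarray


def meta_mom(
    coefs: list[np.ndarray], covs: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Method-of-moments multivariate random-effects meta-analysis.

    Between-study covariance = PSD truncation of the sample covariance of
    the study coefficients minus the mean within-study covariance
    (the multivariate DerSimonian-Laird-type moment estimator); pooling by
    GLS with weights (S_i + B)^-1.
    """
    Th = np.vstack(coefs)
    m, p = Th.shape
    mean = Th.mean(axis=0)
    samp = (Th - mean).T @ (Th - mean) / (m - 1)
    B = samp - np.mean(covs, axis=0)
    vals, vecs = np.linalg.eigh(0.5 * (B + B.T))
    B = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    Wsum = np.zeros((p, p))
    rhs = np.zeros(p)
    for th, S in zip(coefs, covs):
        Wi = _pd_inv(S + B + 1e-12 * np.eye(p))
        Wsum += Wi
        rhs += Wi @ th
    pooled_cov = _pd_inv(Wsum)
    pooled = pooled_cov @ rhs
    return pooled, pooled_cov, B


def two_stage_fit(
    ds: IPDataset,
    target: str,
    predictors: tuple[str, ...],
    family: str,
    min_rows: int = 10,
) -> TwoStageFit:
    """Stage 1 + stage 2 of the two-stage imputation estimator."""
    col = ds.data[target]
    per_study: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for study, rows in ds.data.groupby(ds.cluster_col, sort=False):
        obs = rows.loc[col.loc[rows.index].notna()]
        if len(obs) < min_rows:
            continue
        X = np.column_stack(
            [np.ones(len(obs))] + [obs[p].to_numpy(dtype=float) for p in predictors]
        )
        z = obs[target].to_numpy(dtype=float)
        fitted = _glm_fit_ridge(X, z, family)
        if fitted is None or np.max(np.abs(fitted[0])) > 15:
            warnings.warn(
                f"2STG stage-1 fit failed/separated in study {study}; dropped",
                RuntimeWarning,
            )
            continue
        per_study[study] = fitted
    if len(per_study) < 3:
        raise ImputationError(
            f"2STG needs >= 3 studies with a stable stage-1 fit for {target!r}; "
            f"got {len(per_study)}"
        )
    pooled, pooled_cov, B = meta_mom(
        [c for c, _ in per_study.values()], [S for _, S in per_study.values()]
    )
    return TwoStageFit(per_study, pooled, pooled_cov, B)


def impute_2stg(
    ds: IPDataset,
    target: str,
    predictors: tuple[str, ...] | list[str],
    rng: np.random.Generator,
) -> pd.Series:
    """Two-stage imputation of one variable.

    Study-specific coefficients are drawn from the shrinkage (conditional)
    posterior for studies with a stage-1 fit and from the predictive
    distribution N(mu*, B + V_pooled) otherwise; all missing cells of a
    study — sporadic or systematic — are imputed from that drawn model.
    """
    predictors = tuple(predictors)
    vtype = ds.var_spec(target).vtype
    _require_complete_predictors(ds, predictors)
    family = FAMILY_FOR_VTYPE[vtype]
    tsf = two_stage_fit(ds, target, predictors, family)
    p = len(tsf.pooled_coef)
    B = tsf.between_cov

    mu_star = tsf.pooled_coef + _psd_cholesky(
        tsf.pooled_cov + 1e-12 * np.eye(p)
    ) @ rng.standard_normal(p)

    col = ds.data[target].copy()
    miss = col.isna()
    if not miss.any():
        return col
    for study, srows in ds.data.loc[miss].groupby(ds.cluster_col, sort=False):
        if study in tsf.per_study_coef:
            th, S = tsf.per_study_coef[study]
            # (S^-1 + B^-1)^-1 computed stably as B(S+B)^-1 S
            SpB = _pd_inv(S + B + 1e-12 * np.eye(p))
            mean = B @ SpB @ th + S @ SpB @ mu_star
            cov = B @ SpB @ S
        else:
            mean = mu_star
            cov = B + tsf.pooled_cov
        theta = mean + _psd_cholesky(cov + 1e-12 * np.eye(p)) @ \
            rng.standard_normal(p)
        X = np.column_stack(
            [np.ones(len(srows))]
            + [srows[q].to_numpy(dtype=float) for q in predictors]
        )
        eta = np.clip(X @ theta, -20, 20)
        sigma2 = None
        if family == "gaussian":
            sigma2 = 1.0
        col.loc[srows.index] = _sample_family(family, eta, rng, sigma2)
    return col


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

def cca_filter(ds: IPDataset) -> IPDataset:
    """Complete-case dataset: drop every row missing any analysis variable.

    Studies losing all rows disappear entirely (the CCA arm of the
    benchmark); raises if nothing remains.
    """
    cols = ds.variables()
    keep = ~ds.data[cols].isna().any(axis=1)
    if not keep.any():
        raise ImputationError("complete-case filter removed every row")
    return IPDataset(ds.data.loc[keep].reset_index(drop=True), list(ds.spec))
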