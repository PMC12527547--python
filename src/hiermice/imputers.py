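"""Elementary multilevel imputation of a single incomplete variable.

``impute_mlmi`` performs one full hierarchical imputation step for a binary
or count (or continuous) variable: fit the GLMM on observed rows, draw
(beta*, Omega*, {b*_i}) from the approximate posterior — accept-reject for
studies observing the variable, the prior for systematically missing
studies — and sample the missing cells from the family's distribution at
the drawn linear predictor.  ``impute_normal_hier`` is the continuous
counterpart where the random-effect posterior is available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import IPDataset, classify_missingness
from .glmm import EstimationError, GLMMSpec, INTERCEPT, build_design, fit_glmm
from .param_draws import (
    ParameterDraw,
    _pd_inv,
    _psd_cholesky,
    draw_beta,
    draw_b_systematic,
    draw_omega,
    draw_parameters,
)

__all__ = ["ImputerConfig", "impute_mlmi", "impute_normal_hier", "ImputationError"]

FAMILY_FOR_VTYPE = {"binary": "binomial", "count": "poisson", "continuous": "gaussian"}


class ImputationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImputerConfig:
    """Settings of one elementary imputer.

    ``random_design`` lists the random-effect terms (default: intercept plus
    the analysis outcome, added by the engine).  ``eta_cap`` clips the linear
    predictor before exponentiation; it only bites in pathological tails of
    the Omega* draw.
    """

    family: str
    random_design: tuple[str, ...] = (INTERCEPT,)
    eta_cap: float = 20.0
    max_tries: int = 10_000
    #: EM tolerance of the within-cycle GLMM refits; looser than a final
    #: analysis fit because the chained-equations loop refits every cycle.
    fit_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.eta_cap <= 0:
            raise ValueError("eta_cap must be positive")


def _check_family(ds: IPDataset, target: str, family: str) -> None:
    vtype = ds.var_spec(target).vtype
    if FAMILY_FOR_VTYPE.get(vtype) != family:
        raise ImputationError(
            f"family {family!r} does not match vtype {vtype!r} of {target!r}"
        )


def _prepare(ds: IPDataset, target: str, predictors: tuple[str, ...], cfg: ImputerConfig):
    _check_family(ds, target, cfg.family)
    for p in predictors:
        if ds.data[p].isna().any():
            raise ImputationError(
                f"predictor {p!r} has missing entries; the engine must supply "
                "a current fill"
            )
    pattern = classify_missingness(ds, target)
    n_observing = sum(
        1 for st in pattern.per_study_status.values() if st != "systematic"
    )
    if n_observing == 0:
        raise ImputationError(
            f"variable {target!r} is systematically missing in every study; "
            "imputation impossible"
        )
    random_design = tuple(
        t for t in cfg.random_design if t == INTERCEPT or t in predictors
    )
    if not random_design:
        random_design = (INTERCEPT,)
    # the Omega* draw needs m >= q + 2 contributing studies; fall back to a
    # random intercept only when too few studies observe the target
    if n_observing < len(random_design) + 2 and len(random_design) > 1:
        random_design = (INTERCEPT,)
        if n_observing < 3:
            raise ImputationError(
                f"variable {target!r} observed in only {n_observing} studies; "
                "too few for a hierarchical imputation model"
            )
    spec = GLMMSpec(cfg.family, target, tuple(predictors), ds.cluster_col, random_design)
    return pattern, spec


def _sample_family(
    family: str, eta: np.ndarray, rng: np.random.Generator, sigma2: float | None
) -> np.ndarray:
    """Sample the imputation model's conditional distribution at eta."""
    if family == "binomial":
        return rng.binomial(1, expit(eta)).astype(float)
    if family == "poisson":
        return rng.poisson(np.exp(eta)).astype(float)
    return eta + np.sqrt(sigma2) * rng.standard_normal(len(eta))


def _fill_missing(
    ds: IPDataset,
    target: str,
    spec: GLMMSpec,
    draw: ParameterDraw,
    cfg: ImputerConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Fill each missing cell of ``target`` from the drawn model."""
    col = ds.data[target].copy()
    miss = col.isna()
    if not miss.any():
        return col
    rows = ds.data.loc[miss]
    for study, srows in rows.groupby(ds.cluster_col, sort=False):
        X, Z, _ = build_design(srows, spec, require_response=False)
        b = draw.b_star[study]
        eta = np.clip(X @ draw.beta_star + Z @ b, -cfg.eta_cap, cfg.eta_cap)
        col.loc[srows.index] = _sample_family(spec.family, eta, rng, draw.sigma2_star)
    return col


def impute_mlmi(
    ds: IPDataset,
    target: str,
    predictors: tuple[str, ...] | list[str],
    cfg: ImputerConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """One hierarchical imputation of ``target``; observed cells unchanged.

    Studies where the variable is partially observed contribute to the fit
    and receive accept-reject random-effect draws; systematically missing
    studies receive prior draws N(0, Omega*).
    """
    predictors = tuple(predictors)
    pattern, spec = _prepare(ds, target, predictors, cfg)
    try:
        fit = fit_glmm(ds, spec, tol=cfg.fit_tol)
    except EstimationError as e:
        raise ImputationError(str(e)) from e
    systematic = set(pattern.studies_with("systematic"))
    # studies absent from the fit (no fully observed rows) get prior draws too
    systematic |= set(ds.studies) - set(fit.fitted_clusters)
    draw = draw_parameters(fit, systematic, rng, max_tries=cfg.max_tries)
    return _fill_missing(ds, target, spec, draw, cfg, rng)


def impute_normal_hier(
    ds: IPDataset,
    target: str,
    predictors: tuple[str, ...] | list[str],
    cfg: ImputerConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Hierarchical imputation of a continuous variable (closed-form draws).

    Identical to :func:`impute_mlmi` with the Gaussian family, except the
    random effects of partially observed studies are drawn from their exact
    normal conditional posterior rather than by accept-reject, and the
    residual variance is drawn as sigma2_hat * df / chi2_df.
    """
    predictors = tuple(predictors)
    if cfg.family != "gaussian":
        raise ImputationError("impute_normal_hier requires the gaussian family")
    pattern, spec = _prepare(ds, target, predictors, cfg)
    try:
        fit = fit_glmm(ds, spec, tol=cfg.fit_tol)
    except EstimationError as e:
        raise ImputationError(str(e)) from e

    beta_star = draw_beta(fit, rng)
    omega_star = draw_omega([fit.b_hat[c] for c in fit.fitted_clusters], rng)
    df = max(fit.n_obs - spec.p, 1)
    sigma2_star = float(fit.sigma2_hat * df / rng.chisquare(df))

    systematic = set(pattern.studies_with("systematic"))
    systematic |= set(ds.studies) - set(fit.fitted_clusters)
    omega_inv = _pd_inv(omega_star)
    b_star: dict[str, np.ndarray] = {}
    for study in sorted(systematic):
        b_star[study] = draw_b_systematic(omega_star, rng)
    for study in fit.fitted_clusters:
        if study in systematic:
            continue
        X, Z, z = fit.cluster_data[study]
        # exact Gaussian conditional posterior of b_i given this study's rows
        prec = Z.T @ Z / sigma2_star + omega_inv
        V = _pd_inv(prec)
        mean = V @ (Z.T @ (z - X @ beta_star)) / sigma2_star
        b_star[study] = mean + _psd_cholesky(V) @ rng.standard_normal(spec.q)
    draw = ParameterDraw(beta_star, omega_star, b_star, sigma2_star)
    return _fill_missing(ds, target, spec, draw, cfg, rng)
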