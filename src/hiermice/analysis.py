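"""Analysis-model fitting, Rubin's-rules pooling, and performance metrics.

The analysis model regresses the outcome on the covariates with a random
intercept and a random slope by study (a linear mixed model for a
continuous outcome, a logistic GLMM for a binary one).  Each imputed
dataset is fitted separately and the m results are combined by Rubin's
rules: pooled estimate Qbar, within-variance W, between-variance B, total
variance T = W + (1 + 1/m) B, and t-based 95% intervals with the classical
large-sample degrees of freedom.  Random-effects variances are pooled by
their arithmetic average across imputations.  ``evaluate`` turns replicate
pooled results into the bias / Model SE / Emp SE / coverage / RMSE table of
a simulation study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import IPDataset
from .glmm import GLMMSpec, fit_glmm
from .synthetic import TrueParams

__all__ = ["FitResult", "PooledResult", "MetricsRow", "fit_analysis",
           "pool_rubin", "evaluate", "pooled_from_single"]


@dataclass
class FitResult:
    """Estimates of one completed-data analysis-model fit."""

    estimates: dict[str, float]   # beta0..betap, tau0_sq, tau1_sq, [sigma2]
    ses: dict[str, float]         # fixed effects only
    converged: bool

    @property
    def fixed_names(self) -> list[str]:
        return list(self.ses)


def fit_analysis(
    ds: IPDataset,
    outcome: str | None = None,
    covariates: list[str] | None = None,
    outcome_type: str | None = None,
    random_slope: str | None = None,
) -> FitResult:
    """Fit the analysis GLMM on a complete (or completed) dataset.

    Defaults: outcome/covariates from the dataset's variable roles,
    family from the outcome's variable type, random slope on the first
    covariate.  Returns fixed-effect estimates with SEs plus the
    random-intercept and random-slope variances (and sigma2 if Gaussian).
    """
    outcome = outcome or next(s.name for s in ds.spec if s.role == "outcome")
    covariates = covariates or [v for v in ds.variables(("covariate",))]
    if outcome_type is None:
        outcome_type = (
            "binary" if ds.var_spec(outcome).vtype == "binary" else "continuous"
        )
    family = "gaussian" if outcome_type == "continuous" else "binomial"
    random_slope = covariates[0] if random_slope is None else random_slope
    spec = GLMMSpec(
        family, outcome, tuple(covariates), ds.cluster_col,
        ("intercept", random_slope),
    )
    fit = fit_glmm(ds, spec)
    est = {f"beta{j}": float(b) for j, b in enumerate(fit.beta_hat)}
    ses = {
        f"beta{j}": float(np.sqrt(fit.V_beta[j, j]))
        for j in range(len(fit.beta_hat))
    }
    est["tau0_sq"] = float(fit.Omega_hat[0, 0])
    est["tau1_sq"] = float(fit.Omega_hat[1, 1]) if spec.q > 1 else 0.0
    if family == "gaussian":
        est["sigma2"] = float(fit.sigma2_hat)
    return FitResult(est, ses, fit.converged)


@dataclass
class PooledResult:
    """Rubin's-rules combination of m completed-data fits."""

    qbar: dict[str, float]
    within: dict[str, float]
    between: dict[str, float]
    total_var: dict[str, float]
    df: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    pooled_ranef: dict[str, float]
    m: int

    def estimate(self, name: str) -> float:
        if name in self.qbar:
            return self.qbar[name]
        return self.pooled_ranef[name]

    @property
    def parameters(self) -> list[str]:
        return list(self.qbar) + list(self.pooled_ranef)


def pool_rubin(fits: list[FitResult]) -> PooledResult:
    """Pool m analysis fits by Rubin's rules.

    Fixed effects: Qbar = mean, W = mean squared SE, B = sample variance,
    T = W + (1+1/m)B, df = (m-1)(1 + W/((1+1/m)B))^2, t-based 95% CI.
    Random-effects parameters: arithmetic average of the m estimates.
    """
    if not fits:
        raise ValueError("no fits to pool")
    m = len(fits)
    names = fits[0].fixed_names
    for f in fits[1:]:
        if f.fixed_names != names:
            raise ValueError("inconsistent parameter sets across fits")
    if m == 1:
        warnings.warn("pooling a single imputation: between-variance set to 0",
                      RuntimeWarning)
    qbar, W, B, T, df, ci = {}, {}, {}, {}, {}, {}
    for name in names:
        est = np.array([f.estimates[name] for f in fits])
        se = np.array([f.ses[name] for f in fits])
        qbar[name] = float(est.mean())
        W[name] = float(np.mean(se**2))
        B[name] = float(est.var(ddof=1)) if m > 1 else 0.0
        T[name] = W[name] + (1.0 + 1.0 / m) * B[name]
        if B[name] > 0:
            r = (1.0 + 1.0 / m) * B[name] / W[name]
            df[name] = (m - 1) * (1.0 + 1.0 / r) ** 2
        else:
            df[name] = np.inf
        tcrit = stats.t.ppf(0.975, df[name]) if np.isfinite(df[name]) else 1.959963984540054
        half = tcrit * np.sqrt(T[name])
        ci[name] = (qbar[name] - half, qbar[name] + half)
    ranef_names = [k for k in fits[0].estimates if k not in names]
    pooled_ranef = {
        k: float(np.mean([f.estimates[k] for f in fits])) for k in ranef_names
    }
    return PooledResult(qbar, W, B, T, df, ci, pooled_ranef, m)


def pooled_from_single(fit: FitResult) -> PooledResult:
    """Wrap a single complete-data fit (REF / CCA arms) as a PooledResult."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pool_rubin([fit])


@dataclass
class MetricsRow:
    """Per-parameter simulation performance over replicates."""

    parameter: str
    bias: float
    model_se: float | None
    emp_se: float
    coverage: float | None
    rmse: float
    n_replicates: int

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter, "bias": self.bias,
            "model_se": self.model_se, "emp_se": self.emp_se,
            "coverage": self.coverage, "rmse": self.rmse,
            "n_replicates": self.n_replicates,
        }


def evaluate(
    replicate_results: list[PooledResult], truth: TrueParams | dict[str, float]
) -> list[MetricsRow]:
    """Bias / Model SE / Emp SE / coverage / RMSE over simulation replicates.

    Coverage (and Model SE) are reported for fixed effects only; the
    pooling rule defines no interval for random-effects variances.
    """
    if len(replicate_results) < 2:
        raise ValueError("need >= 2 replicates to evaluate")
    truth_map = truth.as_dict() if isinstance(truth, TrueParams) else dict(truth)
    rows: list[MetricsRow] = []
    n = len(replicate_results)
    for name in replicate_results[0].parameters:
        if name not in truth_map:
            raise KeyError(f"truth does not define parameter {name!r}")
        theta = truth_map[name]
        est = np.array([r.estimate(name) for r in replicate_results])
        bias = float(est.mean() - theta)
        emp_se = float(est.std(ddof=1))
        rmse = float(np.sqrt(np.mean((est - theta) ** 2)))
        if name in replicate_results[0].qbar:
            model_se = float(
                np.mean([np.sqrt(r.total_var[name]) for r in replicate_results])
            )
            cover = float(
                np.mean([
                    r.ci95[name][0] <= theta <= r.ci95[name][1]
                    for r in replicate_results
                ])
            )
        else:
            model_se = None
            cover = None
        rows.append(MetricsRow(name, bias, model_se, emp_se, cover, rmse, n))
    return rows


def metrics_frame(rows: list[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])
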