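"""Synthetic IPD meta-analysis data with known truth and missingness.

The generator emulates a CKD-style IPD-MA: per study a binary covariate x1
(e.g. alcohol consumption), a count covariate x2 (number of comorbidities)
and an outcome y (smoking status, binary — or a continuous analogue), with
study-level random effects on both the covariate and the outcome models:

    x1_ij ~ Bernoulli(expit(alpha0 + a_i1))
    x2_ij ~ Poisson(exp(gamma0 + gamma1 x1_ij + a_i2)),  (a_i1, a_i2) ~ N(0, Psi)
    continuous: y_ij = beta0 + beta1 x1 + beta2 x2 + u_i0 + u_i1 x1 + eps
    binary:     y_ij ~ Bernoulli(expit(beta0 + beta1 x1 + beta2 x2 + u_i0 + u_i1 x1))

with (u_i0, u_i1) ~ N(0, T).  Missingness is imposed afterwards: whole
(variable, study) pairs are erased with probability pi (systematic, MCAR)
and remaining cells are erased sporadically under MCAR or MAR where the
missingness probability depends on the fully observed outcome through
expit(psi0 + slope * y), with psi0 calibrated to hit the target rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_model import IPDataset, VariableSpec

__all__ = [
    "SimConfig",
    "TrueParams",
    "generate_ipd",
    "impose_systematic",
    "impose_sporadic",
    "systematic_pattern",
    "calibrate_intercept",
    "scenario_grid",
    "HETEROGENEITY",
]

#: Random-effect variance per heterogeneity level (applied to both the
#: outcome covariance T and the covariate covariance Psi; correlation 0.3).
HETEROGENEITY = {"weak": 0.05, "moderate": 0.2, "strong": 0.5}
RE_CORRELATION = 0.3

N_STUDIES_GRID = (6, 10, 15, 20, 30)
TOTAL_N = 3000


def _re_cov(tau2: float) -> np.ndarray:
    off = RE_CORRELATION * tau2
    return np.array([[tau2, off], [off, tau2]])


@dataclass(frozen=True)
class TrueParams:
    """Generating parameters; the recovery targets of every simulation."""

    beta: tuple[float, float, float] = (-0.5, 0.4, 0.2)
    tau: tuple[float, float, float] = (0.2, 0.2, 0.06)  # (tau0^2, tau1^2, tau01)
    sigma2: float = 1.0
    alpha0: float = -0.3
    gamma: tuple[float, float] = (0.8, 0.2)
    psi: np.ndarray = field(default_factory=lambda: _re_cov(0.2))

    def outcome_cov(self) -> np.ndarray:
        t0, t1, t01 = self.tau
        return np.array([[t0, t01], [t01, t1]])

    def as_dict(self) -> dict[str, float]:
        d = {
            "beta0": self.beta[0], "beta1": self.beta[1], "beta2": self.beta[2],
            "tau0_sq": self.tau[0], "tau1_sq": self.tau[1], "tau01": self.tau[2],
            "sigma2": self.sigma2,
        }
        return d


@dataclass(frozen=True)
class SimConfig:
    """One cell of the simulation design.

    ``per_study`` defaults to the fixed 3000-participant total divided
    equally among the studies, as in the benchmark grid.
    """

    outcome_type: str = "binary"
    n_studies: int = 10
    per_study: int | None = None
    heterogeneity: str = "weak"
    pi_systematic: float = 0.10
    sporadic_rate: float = 0.10
    mechanism: str = "MCAR"
    mar_slopes: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.heterogeneity not in HETEROGENEITY:
            raise ValueError(f"unknown heterogeneity {self.heterogeneity!r}")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.pi_systematic < 1.0:
            raise ValueError("pi_systematic must be in [0, 1)")
        if not 0.0 <= self.sporadic_rate < 1.0:
            raise ValueError("sporadic_rate must be in [0, 1)")

    @property
    def study_size(self) -> int:
        if self.per_study is not None:
            return self.per_study
        if TOTAL_N % self.n_studies:
            raise ValueError(
                f"{self.n_studies} studies do not divide the {TOTAL_N} total; "
                "set per_study explicitly"
            )
        return TOTAL_N // self.n_studies

    def truth(self) -> TrueParams:
        tau2 = HETEROGENEITY[self.heterogeneity]
        return TrueParams(
            tau=(tau2, tau2, RE_CORRELATION * tau2), psi=_re_cov(tau2)
        )


IPD_SPEC = [
    VariableSpec("study", "cluster_id", "cluster"),
    VariableSpec("x1", "binary", "covariate"),
    VariableSpec("x2", "count", "covariate"),
]


def generate_ipd(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    truth: TrueParams | None = None,
) -> tuple[IPDataset, TrueParams]:
    """Generate one complete dataset (before missingness) plus its truth.

    ``truth`` overrides the parameters implied by the heterogeneity label
    (useful for boundary cases such as zero heterogeneity).
    """
    truth = cfg.truth() if truth is None else truth
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_i = cfg.study_size
    frames = []
    a = rng.multivariate_normal(np.zeros(2), truth.psi, size=cfg.n_studies)
    u = rng.multivariate_normal(np.zeros(2), truth.outcome_cov(), size=cfg.n_studies)
    b0, b1, b2 = truth.beta
    g0, g1 = truth.gamma
    for i in range(cfg.n_studies):
        x1 = rng.binomial(1, expit(truth.alpha0 + a[i, 0]), size=n_i).astype(float)
        x2 = rng.poisson(np.exp(g0 + g1 * x1 + a[i, 1])).astype(float)
        lin = b0 + b1 * x1 + b2 * x2 + u[i, 0] + u[i, 1] * x1
        if cfg.outcome_type == "continuous":
            y = lin + np.sqrt(truth.sigma2) * rng.standard_normal(n_i)
        else:
            y = rng.binomial(1, expit(lin)).astype(float)
        frames.append(
            pd.DataFrame({"study": f"s{i + 1:02d}", "x1": x1, "x2": x2, "y": y})
        )
    spec = IPD_SPEC + [
        VariableSpec(
            "y", "continuous" if cfg.outcome_type == "continuous" else "binary",
            "outcome",
        )
    ]
    return IPDataset(pd.concat(frames, ignore_index=True), spec), truth


# ---------------------------------------------------------------------------
# missingness mechanisms
# ---------------------------------------------------------------------------

def systematic_pattern(
    n_studies: int, n_vars: int, pi: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_studies, n_vars) matrix: True = erase that pair entirely."""
    return rng.uniform(size=(n_studies, n_vars)) < pi


def impose_systematic(
    ds: IPDataset,
    variables: list[str],
    pi: float,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> IPDataset:
    """Erase whole (variable, study) pairs with probability pi, MCAR.

    The pattern is redrawn (up to ``max_attempts`` times) until every
    variable remains observed in at least 2 studies, so downstream mixed
    models stay estimable.
    """
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must be in [0, 1)")
    studies = ds.studies
    for _ in range(max_attempts):
        pattern = systematic_pattern(len(studies), len(variables), pi, rng)
        if all((~pattern[:, j]).sum() >= 2 for j in range(len(variables))):
            break
    else:
        raise ValueError(
            f"could not draw a systematic pattern leaving every variable in "
            f">= 2 studies within {max_attempts} attempts (pi={pi})"
        )
    out = ds.copy()
    labels = out.data[out.cluster_col]
    for j, var in enumerate(variables):
        for i, study in enumerate(studies):
            if pattern[i, j]:
                out.data.loc[labels == study, var] = np.nan
    return out


def calibrate_intercept(
    y: np.ndarray, slope: float, target_rate: float, tol: float = 1e-6
) -> float:
    """Solve mean_j expit(psi0 + slope*y_j) = target_rate for psi0.

    Monotone bisection on the realized outcome sample; for slope = 0 the
    closed form logit(target_rate) is returned exactly.
    """
    if slope == 0.0:
        return float(logit(target_rate))
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0.0:
        # degenerate outcome: closed form through psi0 alone
        return float(logit(target_rate) - slope * y[0])

    def rate(psi0: float) -> float:
        return float(np.mean(expit(psi0 + slope * y)))

    lo, hi = -50.0, 50.0
    if not rate(lo) <= target_rate <= rate(hi):
        raise ValueError("target rate unreachable for this outcome sample")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def impose_sporadic(
    ds: IPDataset,
    var: str,
    mechanism: str,
    target_rate: float,
    slope: float,
    rng: np.random.Generator,
) -> IPDataset:
    """Erase cells of ``var`` sporadically at ``target_rate``.

    MCAR erases uniformly; MAR erases with probability expit(psi0 +
    slope*y) where psi0 is calibrated on the realized outcome sample.  Only
    studies where ``var`` is not already systematically missing are
    touched; the outcome must be complete.
    """
    out = ds.copy()
    outcome = next(s.name for s in ds.spec if s.role == "outcome")
    if out.data[outcome].isna().any():
        raise ValueError("sporadic MAR mechanism requires a complete outcome")
    col = out.data[var]
    labels = out.data[out.cluster_col]
    observing = [
        s for s in out.studies if col[labels == s].notna().any()
    ]
    eligible = labels.isin(observing) & col.notna()
    idx = out.data.index[eligible]
    if mechanism == "MCAR" or slope == 0.0:
        prob = np.full(len(idx), target_rate)
    else:
        y = out.data.loc[idx, outcome].to_numpy(dtype=float)
        psi0 = calibrate_intercept(y, slope, target_rate)
        prob = expit(psi0 + slope * y)
    erase = rng.uniform(size=len(idx)) < prob
    out.data.loc[idx[erase], var] = np.nan
    return out


def make_incomplete(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[IPDataset, IPDataset, TrueParams]:
    """Generate a dataset and impose the configured missingness.

    Returns (complete, incomplete, truth); the complete copy is the REF arm
    of the benchmark.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    complete, truth = generate_ipd(cfg, rng)
    ds = impose_systematic(complete, ["x1", "x2"], cfg.pi_systematic, rng)
    slopes = cfg.mar_slopes if cfg.mechanism == "MAR" else (0.0, 0.0)
    ds = impose_sporadic(ds, "x1", cfg.mechanism, cfg.sporadic_rate, slopes[0], rng)
    ds = impose_sporadic(ds, "x2", cfg.mechanism, cfg.sporadic_rate, slopes[1], rng)
    return complete, ds, truth


def scenario_grid() -> list[SimConfig]:
    """The full factorial benchmark grid: 2 outcomes x 3 heterogeneity
    levels x 5 study counts x 2 systematic proportions x 2 mechanisms."""
    grid = []
    for outcome in ("continuous", "binary"):
        for het in ("weak", "moderate", "strong"):
            for n in N_STUDIES_GRID:
                for pi in (0.10, 0.25):
                    for mech in ("MCAR", "MAR"):
                        slope = 0.5 if outcome == "continuous" else 1.0
                        grid.append(
                            SimConfig(
                                outcome_type=outcome, n_studies=n,
                                heterogeneity=het, pi_systematic=pi,
                                mechanism=mech, mar_slopes=(slope, slope),
                            )
                        )
    return grid


def scenario_id(cfg: SimConfig) -> str:
    return (
        f"{cfg.outcome_type}-{cfg.heterogeneity}-n{cfg.n_studies}"
        f"-pi{int(round(100 * cfg.pi_systematic))}-{cfg.mechanism}"
    )
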