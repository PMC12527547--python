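"""Chained-equations orchestration: initial fill, visit sequence, cycles, chains.

Each of the m imputation chains starts from a random initial fill, then
sweeps the incomplete variables in the visit order for a fixed number of
cycles, calling the mapped elementary imputer with all other variables
(current fill) as predictors.  The final cycle's completion of each chain
is one imputed dataset.  Chains use independent random sub-streams spawned
from the seed, so runs are reproducible and embarrassingly parallel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comparators import impute_2stg, impute_sti
from .data_model import IPDataset, write_ipd
from .glmm import INTERCEPT
from .imputers import (
    FAMILY_FOR_VTYPE,
    ImputationError,
    ImputerConfig,
    impute_mlmi,
    impute_normal_hier,
)

__all__ = ["MiceConfig", "ImputedStack", "run_mice", "initial_fill", "MiceError"]

METHODS = ("mlmi", "sti", "2stg", "normal_hier")


class MiceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MiceConfig:
    """Configuration of one chained-equations run.

    ``method_map`` assigns an elementary method to every incomplete
    variable; ``visit`` is an explicit variable order or ``"monotone-auto"``
    (ascending missing fraction).  ``predictors`` optionally overrides the
    default all-other-variables predictor set per variable (e.g. to add
    auxiliary variables or drop one).  ``random_design`` optionally fixes
    the random-effect terms of the hierarchical imputers; the default is a
    random intercept plus a random slope on the analysis outcome.
    """

    m: int = 5
    cycles: int = 10
    visit: str | tuple[str, ...] = "monotone-auto"
    method_map: dict[str, str] = field(default_factory=dict)
    predictors: dict[str, tuple[str, ...]] = field(default_factory=dict)
    random_design: tuple[str, ...] | None = None
    outcome: str | None = None
    seed: int = 0
    eta_cap: float = 20.0
    max_tries: int = 10_000

    def __post_init__(self) -> None:
        if self.m < 1 or self.cycles < 1:
            raise ValueError("m and cycles must be >= 1")
        for v, meth in self.method_map.items():
            if meth not in METHODS:
                raise ValueError(f"unknown method {meth!r} for {v!r}")


@dataclass
class ImputedStack:
    """m completed datasets plus per-chain convergence summaries."""

    completed: list[IPDataset]
    chain_log: pd.DataFrame  # columns: chain, cycle, variable, mean_imputed
    config: MiceConfig

    @property
    def m(self) -> int:
        return len(self.completed)

    def save(self, directory) -> None:
        """One CSV per completed dataset plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = []
        for i, ds in enumerate(self.completed, start=1):
            name = f"imputed_{i}.csv"
            write_ipd(ds, directory / name)
            files.append(name)
        manifest = {
            "m": self.m,
            "seed": self.config.seed,
            "cycles": self.config.cycles,
            "method_map": dict(self.config.method_map),
            "files": files,
            "chain_log": self.chain_log.to_dict(orient="list"),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def initial_fill(ds: IPDataset, rng: np.random.Generator) -> IPDataset:
    """Fill each missing cell by sampling from observed values in the same
    study; studies observing nothing (systematic) sample from the pooled
    observed values."""
    out = ds.copy()
    for var in ds.variables():
        col = out.data[var]
        miss = col.isna()
        if not miss.any():
            continue
        pooled = col.dropna().to_numpy()
        if len(pooled) == 0:
            raise MiceError(f"variable {var!r} observed nowhere; cannot fill")
        for study, srows in out.data.loc[miss].groupby(ds.cluster_col, sort=False):
            in_study = col[out.data[ds.cluster_col] == study].dropna().to_numpy()
            pool = in_study if len(in_study) else pooled
            out.data.loc[srows.index, var] = rng.choice(pool, size=len(srows))
    return out


def _visit_order(ds: IPDataset, cfg: MiceConfig, incomplete: list[str]) -> list[str]:
    if cfg.visit == "monotone-auto":
        fracs = {v: float(ds.data[v].isna().mean()) for v in incomplete}
        return sorted(incomplete, key=lambda v: (fracs[v], incomplete.index(v)))
    order = [v for v in cfg.visit if v in incomplete]
    if set(order) != set(incomplete):
        raise MiceError("visit sequence does not cover all incomplete variables")
    return order


def _impute_one(ds, var, predictors, method, cfg: MiceConfig, rng) -> pd.Series:
    vtype = ds.var_spec(var).vtype
    if method in ("mlmi", "normal_hier"):
        rd = cfg.random_design
        if rd is None:
            rd = (INTERCEPT, cfg.outcome) if cfg.outcome in predictors \
                else (INTERCEPT,)
        family = FAMILY_FOR_VTYPE[vtype]
        icfg = ImputerConfig(family, tuple(rd), cfg.eta_cap, cfg.max_tries)
        fn = impute_normal_hier if method == "normal_hier" else impute_mlmi
        return fn(ds, var, predictors, icfg, rng)
    if method == "sti":
        return impute_sti(ds, var, predictors, rng)
    return impute_2stg(ds, var, predictors, rng)


def _run_chain(ds: IPDataset, cfg: MiceConfig, visit, rng, chain_idx, log_rows):
    work = initial_fill(ds, rng)
    orig = {v: ds.data[v] for v in visit}
    masks = {v: ds.data[v].isna() for v in visit}
    for cycle in range(1, cfg.cycles + 1):
        for var in visit:
            # restore the variable's true missingness before re-imputing it
            work.data[var] = orig[var].copy()
            predictors = cfg.predictors.get(
                var, tuple(v for v in work.variables() if v != var)
            )
            col = _impute_one(work, var, predictors, cfg.method_map[var], cfg, rng)
            work.data[var] = col
            log_rows.append(
                (chain_idx, cycle, var, float(col[masks[var]].mean()))
            )
    return work


def run_mice(ds: IPDataset, cfg: MiceConfig) -> ImputedStack:
    """Run m independent chained-equation imputation chains.

    A chain that fails mid-run is restarted once with a fresh sub-stream; a
    second failure aborts the run naming the variable and cycle.
    """
    incomplete = [v for v in ds.variables() if ds.data[v].isna().any()]
    uncovered = [v for v in incomplete if v not in cfg.method_map]
    if uncovered:
        raise MiceError(f"no imputation method mapped for {uncovered}")
    if not incomplete:
        return ImputedStack(
            [ds.copy() for _ in range(cfg.m)],
            pd.DataFrame(columns=["chain", "cycle", "variable", "mean_imputed"]),
            cfg,
        )
    visit = _visit_order(ds, cfg, incomplete)
    streams = np.random.SeedSequence(cfg.seed).spawn(2 * cfg.m)
    completed: list[IPDataset] = []
    log_rows: list[tuple] = []
    for k in range(cfg.m):
        rng = np.random.default_rng(streams[k])
        try:
            completed.append(_run_chain(ds, cfg, visit, rng, k + 1, log_rows))
        except (ImputationError, np.linalg.LinAlgError) as first:
            warnings.warn(
                f"chain {k + 1} failed ({first}); restarting with a new "
                "sub-stream", RuntimeWarning,
            )
            rng = np.random.default_rng(streams[cfg.m + k])
            try:
                completed.append(_run_chain(ds, cfg, visit, rng, k + 1, log_rows))
            except (ImputationError, np.linalg.LinAlgError) as second:
                raise MiceError(
                    f"chain {k + 1} failed twice: {second}"
                ) from second
    log = pd.DataFrame(
        log_rows, columns=["chain", "cycle", "variable", "mean_imputed"]
    )
    return ImputedStack(completed, log, cfg)
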