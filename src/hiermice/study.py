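"""Simulation-study driver: one replicate, one scenario, metric tables.

A replicate generates a complete dataset, imposes missingness, and runs
each requested arm — REF (fit before missingness), CCA, and the multiple-
imputation methods (MLMI, STI, 2STG) with Rubin pooling — returning one
PooledResult per arm.  A scenario repeats this and reduces to the
bias/SE/coverage/RMSE table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .analysis import (
    PooledResult,
    evaluate,
    fit_analysis,
    metrics_frame,
    pool_rubin,
    pooled_from_single,
)
from .comparators import cca_filter
from .mice import MiceConfig, run_mice
from .synthetic import SimConfig, TrueParams, make_incomplete

__all__ = ["run_replicate", "run_scenario", "ARMS"]

ARMS = ("REF", "CCA", "STI", "MLMI", "2STG")
MI_METHOD = {"MLMI": "mlmi", "STI": "sti", "2STG": "2stg"}


def run_replicate(
    cfg: SimConfig,
    seed: int,
    methods: tuple[str, ...] = ARMS,
    m: int = 5,
    cycles: int = 10,
) -> tuple[dict[str, PooledResult], TrueParams]:
    """Run one simulation replicate and return per-arm pooled results.

    An arm that fails on a given replicate (e.g. 2STG with too few stable
    stage-1 fits) is reported as absent rather than aborting the replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, cfg.seed]))
    complete, incomplete, truth = make_incomplete(cfg, rng)
    chain_seed = int(rng.integers(2**31 - 1))
    out: dict[str, PooledResult] = {}
    for arm in methods:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if arm == "REF":
                    out[arm] = pooled_from_single(fit_analysis(complete))
                elif arm == "CCA":
                    out[arm] = pooled_from_single(fit_analysis(cca_filter(incomplete)))
                else:
                    mcfg = MiceConfig(
                        m=m, cycles=cycles,
                        method_map={"x1": MI_METHOD[arm], "x2": MI_METHOD[arm]},
                        outcome="y", seed=chain_seed,
                    )
                    stack = run_mice(incomplete, mcfg)
                    fits = [fit_analysis(d) for d in stack.completed]
                    out[arm] = pool_rubin(fits)
        except Exception as e:  # noqa: BLE001 — one arm must not sink the replicate
            warnings.warn(f"arm {arm} failed on this replicate: {e}", RuntimeWarning)
    return out, truth


def run_scenario(
    cfg: SimConfig,
    replicates: int,
    seed: int,
    methods: tuple[str, ...] = ARMS,
    m: int = 5,
    cycles: int = 10,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Replicate a scenario and tabulate per-arm, per-parameter metrics.

    Replicates are independent; ``n_jobs > 1`` runs them in parallel
    (joblib), with results identical to the serial order.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    per_arm: dict[str, list[PooledResult]] = {arm: [] for arm in methods}
    truth: TrueParams | None = None
    if n_jobs == 1:
        outs = [run_replicate(cfg, seed + r, methods, m=m, cycles=cycles)
                for r in range(replicates)]
    else:
        from joblib import Parallel, delayed

        outs = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(cfg, seed + r, methods, m=m, cycles=cycles)
            for r in range(replicates)
        )
    for results, truth in outs:
        for arm, res in results.items():
            per_arm[arm].append(res)
    frames = []
    for arm in methods:
        if len(per_arm[arm]) < 2:
            continue
        rows = evaluate(per_arm[arm], truth)
        df = metrics_frame(rows)
        df.insert(0, "method", arm)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
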