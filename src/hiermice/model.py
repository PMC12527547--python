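"""Model/Results front end for multilevel multiple imputation.

``MultilevelMICE`` is constructed from the data (an :class:`IPDataset` or a
plain DataFrame plus variable types); ``fit()`` runs the chained-equations
imputation and returns a results object holding the m completed datasets,
whose ``pool()`` fits the analysis mixed model on each completion and
combines the estimates by Rubin's rules into pooled coefficients, standard
errors, confidence intervals and a printable summary table.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import data_model
from .analysis import PooledResult, fit_analysis, pool_rubin
from .data_model import IPDataset
from .mice import ImputedStack, MiceConfig, run_mice

__all__ = ["MultilevelMICE", "MultilevelMICEResults", "PooledMIResults"]


class MultilevelMICE:
    """Multilevel multiple imputation of an incomplete clustered dataset.

    Parameters
    ----------
    data
        An :class:`IPDataset`, or a DataFrame (then ``cluster`` and
        ``vtypes`` are required).
    methods
        Imputation method per incomplete variable; default ``"mlmi"`` for
        binary/count variables and ``"normal_hier"`` for continuous ones.
    outcome
        The analysis outcome; it enters every imputation model and carries
        the random slope of the hierarchical imputers.
    """

    def __init__(
        self,
        data: IPDataset | pd.DataFrame,
        cluster: str | None = None,
        vtypes: Mapping[str, str] | None = None,
        outcome: str | None = None,
        methods: Mapping[str, str] | None = None,
        predictors: Mapping[str, tuple[str, ...]] | None = None,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            if cluster is None or vtypes is None:
                raise ValueError("DataFrame input requires cluster= and vtypes=")
            data = data_model.from_dataframe(data, cluster, vtypes, outcome)
        self.dataset = data
        self.outcome = outcome or next(
            (s.name for s in data.spec if s.role == "outcome"), None
        )
        self.incomplete = [
            v for v in data.variables() if data.data[v].isna().any()
        ]
        default = {
            v: ("normal_hier" if data.var_spec(v).vtype == "continuous" else "mlmi")
            for v in self.incomplete
        }
        self.methods = {**default, **dict(methods or {})}
        self.predictors = dict(predictors or {})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cluster: str, vtypes, **kw):
        return cls(df, cluster=cluster, vtypes=vtypes, **kw)

    def fit(
        self, m: int = 5, cycles: int = 10, seed: int = 0, **kw
    ) -> "MultilevelMICEResults":
        """Run m chains of the chained-equations sampler."""
        cfg = MiceConfig(
            m=m, cycles=cycles, method_map=self.methods,
            predictors=self.predictors, outcome=self.outcome, seed=seed, **kw,
        )
        return MultilevelMICEResults(self, run_mice(self.dataset, cfg))


class MultilevelMICEResults:
    """The m completed datasets of one imputation run."""

    def __init__(self, model: MultilevelMICE, stack: ImputedStack) -> None:
        self.model = model
        self.stack = stack

    @property
    def datasets(self) -> list[IPDataset]:
        return self.stack.completed

    @property
    def chain_log(self) -> pd.DataFrame:
        return self.stack.chain_log

    def save(self, directory) -> None:
        self.stack.save(directory)

    def pool(
        self,
        outcome: str | None = None,
        covariates: list[str] | None = None,
        outcome_type: str | None = None,
        random_slope: str | None = None,
    ) -> "PooledMIResults":
        """Fit the analysis mixed model per completion and pool (Rubin)."""
        fits = [
            fit_analysis(d, outcome=outcome or self.model.outcome,
                         covariates=covariates, outcome_type=outcome_type,
                         random_slope=random_slope)
            for d in self.datasets
        ]
        return PooledMIResults(pool_rubin(fits), self)


class PooledMIResults:
    """Pooled analysis-model estimates with Rubin's-rules uncertainty."""

    def __init__(self, pooled: PooledResult, parent=None) -> None:
        self._pooled = pooled
        self._parent = parent

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._pooled.qbar)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {k: np.sqrt(v) for k, v in self._pooled.total_var.items()}
        )

    @property
    def df(self) -> pd.Series:
        return pd.Series(self._pooled.df)

    @property
    def pooled_ranef(self) -> pd.Series:
        return pd.Series(self._pooled.pooled_ranef)

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(self._pooled.ci95, index=["lower", "upper"]).T

    def summary(self) -> str:
        pooled = self._pooled
        lines = [
            "Multilevel Multiple Imputation — pooled analysis (Rubin's rules)",
            f"m = {pooled.m} imputations",
            "",
            f"{'parameter':<10}{'estimate':>10}{'std err':>10}"
            f"{'[0.025':>10}{'0.975]':>10}{'df':>10}",
        ]
        for name in pooled.qbar:
            lo, hi = pooled.ci95[name]
            dfv = pooled.df[name]
            dfs = f"{dfv:,.1f}" if np.isfinite(dfv) else "inf"
            lines.append(
                f"{name:<10}{pooled.qbar[name]:>10.4f}"
                f"{np.sqrt(pooled.total_var[name]):>10.4f}"
                f"{lo:>10.4f}{hi:>10.4f}{dfs:>10}"
            )
        if pooled.pooled_ranef:
            lines.append("")
            lines.append("random-effects parameters (arithmetic mean over imputations)")
            for name, v in pooled.pooled_ranef.items():
                lines.append(f"{name:<10}{v:>10.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return self.summary()
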