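"""Clustered-data container, missingness-pattern classification, and I/O.

Individual participant data (IPD) from several studies are held in long
format: one row per participant, one column naming the study (cluster),
plus variables of mixed type (binary, count, continuous).  Missing entries
are encoded by NaN in memory and by an empty cell in CSV/TSV, never by
dropping rows, so imputed copies always align positionally with the
original dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "IPDataset",
    "MissingnessPattern",
    "load_ipd",
    "write_ipd",
    "classify_missingness",
    "SchemaError",
    "DomainError",
]

VTYPES = ("binary", "count", "continuous", "cluster_id")
ROLES = ("outcome", "covariate", "cluster")


class SchemaError(ValueError):
    """A required column is absent or the variable specification is malformed."""


class DomainError(ValueError):
    """An observed value violates its declared variable type."""


@dataclass(frozen=True)
class VariableSpec:
    """Name, type and analysis role of one column.

    vtype is one of ``binary`` (values in {0,1}), ``count`` (non-negative
    integers), ``continuous``, or ``cluster_id`` (the study label column).
    """

    name: str
    vtype: str
    role: str

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise SchemaError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if (self.vtype == "cluster_id") != (self.role == "cluster"):
            raise SchemaError(
                f"{self.name!r}: cluster_id vtype and cluster role must coincide"
            )


@dataclass
class IPDataset:
    """Long-format clustered dataset with explicit missingness.

    ``data`` holds one float64 column per non-cluster variable (NaN marks a
    missing cell) and one object/str column for the cluster labels.  Row
    order is preserved by every operation in the package.
    """

    data: pd.DataFrame
    spec: list[VariableSpec]

    def __post_init__(self) -> None:
        cluster_specs = [s for s in self.spec if s.vtype == "cluster_id"]
        if len(cluster_specs) != 1:
            raise SchemaError("exactly one variable must have vtype cluster_id")
        for s in self.spec:
            if s.name not in self.data.columns:
                raise SchemaError(f"column {s.name!r} missing from data")
        if self.data[self.cluster_col].isna().any():
            raise SchemaError("cluster labels must be complete")
        self.data = self.data.loc[:, [s.name for s in self.spec]].reset_index(drop=True)
        for s in self.spec:
            if s.vtype == "cluster_id":
                self.data[s.name] = self.data[s.name].astype(str)
            else:
                col = pd.to_numeric(self.data[s.name], errors="raise").astype(float)
                self.data[s.name] = col
                _check_domain(col, s)

    # -- basic accessors -------------------------------------------------

    @property
    def cluster_col(self) -> str:
        return next(s.name for s in self.spec if s.vtype == "cluster_id")

    @property
    def studies(self) -> list[str]:
        """Distinct cluster labels in order of first appearance."""
        return list(dict.fromkeys(self.data[self.cluster_col]))

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def study_sizes(self) -> dict[str, int]:
        counts = self.data[self.cluster_col].value_counts()
        return {s: int(counts[s]) for s in self.studies}

    def var_spec(self, name: str) -> VariableSpec:
        for s in self.spec:
            if s.name == name:
                return s
        raise KeyError(f"no variable named {name!r}")

    def variables(self, roles: Iterable[str] = ("outcome", "covariate")) -> list[str]:
        return [s.name for s in self.spec if s.role in roles]

    def missing_mask(self, var: str) -> np.ndarray:
        self.var_spec(var)
        return self.data[var].isna().to_numpy()

    def copy(self) -> "IPDataset":
        return IPDataset(self.data.copy(), list(self.spec))

    def equals(self, other: "IPDataset") -> bool:
        if [s.name for s in self.spec] != [s.name for s in other.spec]:
            return False
        return self.data.equals(other.data)


def _check_domain(col: pd.Series, s: VariableSpec) -> None:
    obs = col.dropna()
    if s.vtype == "binary" and not obs.isin([0.0, 1.0]).all():
        bad = obs[~obs.isin([0.0, 1.0])].iloc[0]
        raise DomainError(f"binary variable {s.name!r} contains value {bad!r}")
    if s.vtype == "count":
        if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
            raise DomainError(f"count variable {s.name!r} must be non-negative integer")


@dataclass
class MissingnessPattern:
    """Per-study missingness status of one variable.

    A variable is *systematic* in a study when it has zero observed values
    there, *complete* when it has zero missing values, and *sporadic*
    otherwise (with 0 < missing fraction < 1).
    """

    variable: str
    per_study_status: dict[str, str]
    sporadic_fraction: dict[str, float] = field(default_factory=dict)

    def studies_with(self, status: str) -> list[str]:
        return [s for s, st in self.per_study_status.items() if st == status]

    @property
    def any_missing(self) -> bool:
        return any(st != "complete" for st in self.per_study_status.values())


def classify_missingness(ds: IPDataset, var: str) -> MissingnessPattern:
    """Classify each study as complete / sporadic / systematic for ``var``."""
    if var == ds.cluster_col:
        raise KeyError("cannot classify the cluster column")
    ds.var_spec(var)
    miss = ds.data[var].isna()
    status: dict[str, str] = {}
    frac: dict[str, float] = {}
    grouped = miss.groupby(ds.data[ds.cluster_col], sort=False)
    agg = grouped.agg(["sum", "count"])
    for study in ds.studies:
        n_miss, n = int(agg.loc[study, "sum"]), int(agg.loc[study, "count"])
        if n_miss == n:
            status[study] = "systematic"
        elif n_miss == 0:
            status[study] = "complete"
        else:
            status[study] = "sporadic"
            frac[study] = n_miss / n
    return MissingnessPattern(var, status, frac)


def load_ipd(path, spec: list[VariableSpec], sep: str = ",") -> IPDataset:
    """Read a delimited text file into an :class:`IPDataset`.

    Empty cells become missing; a cell that cannot be parsed as a number in
    a numeric column raises, as does a binary column containing values
    outside {0, 1}.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    names = [s.name for s in spec]
    absent = [n for n in names if n not in df.columns]
    if absent:
        raise SchemaError(f"missing required column(s): {absent}")
    out = pd.DataFrame(index=df.index)
    for s in spec:
        raw = df[s.name]
        if s.vtype == "cluster_id":
            out[s.name] = raw.astype(str)
        else:
            out[s.name] = pd.to_numeric(raw.replace("", np.nan), errors="raise")
    return IPDataset(out, list(spec))


def write_ipd(ds: IPDataset, path, sep: str = ",") -> None:
    """Write the dataset back out; missing cells become empty fields.

    ``write_ipd`` and :func:`load_ipd` round-trip observed values and the
    missingness mask exactly.
    """
    out = pd.DataFrame(index=ds.data.index)
    for s in ds.spec:
        col = ds.data[s.name]
        if s.vtype == "cluster_id":
            out[s.name] = col
        elif s.vtype in ("binary", "count"):
            out[s.name] = col.map(lambda v: "" if pd.isna(v) else str(int(v)))
        else:
            out[s.name] = col.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep=sep, index=False)


def from_dataframe(
    df: pd.DataFrame,
    cluster: str,
    vtypes: Mapping[str, str],
    outcome: str | None = None,
) -> IPDataset:
    """Build an IPDataset from a plain DataFrame.

    ``vtypes`` maps each non-cluster column to its variable type; ``outcome``
    (optional) marks one column's role as outcome, the rest are covariates.
    """
    spec = [VariableSpec(cluster, "cluster_id", "cluster")]
    for name, vt in vtypes.items():
        role = "outcome" if name == outcome else "covariate"
        spec.append(VariableSpec(name, vt, role))
    return IPDataset(df[[s.name for s in spec]].copy(), spec)
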