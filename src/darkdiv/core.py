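"""Core data containers and tabular I/O for species-pool estimation.

The central objects are thin, validated wrappers around pandas DataFrames:

* :class:`OccurrenceMatrix` — plots x species presences or percent covers;
* :class:`IndicatorTable` — species x ecological-preference dimensions
  (light, temperature, moisture, soil reaction, nutrients by default);
* :class:`EnvTable` — plots x environmental covariates;
* :class:`HabitatAssignment` — plot -> habitat mapping;
* :class:`ExpertPoolTable` — habitat -> (species, affinity grade) lists;
* :class:`PoolEstimate` — a method's plots x species pool membership,
  optionally with per-species probabilities;
* :class:`DarkDiversity` — pool membership minus observed presences.

All containers sort plot and species identifiers lexicographically so that
downstream outputs are byte-stable regardless of input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_DIMS",
    "ValidationError",
    "OccurrenceMatrix",
    "IndicatorTable",
    "HabitatAssignment",
    "EnvTable",
    "ExpertPoolTable",
    "PoolEstimate",
    "DarkDiversity",
    "read_occurrence",
    "dark_from_pool",
    "expert_pool",
]

#: Default indicator-value dimensions (Central European convention).
INDICATOR_DIMS = ("light", "temperature", "moisture", "reaction", "nutrients")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _require_unique(ids: Iterable, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class OccurrenceMatrix:
    """Plots x species occurrence table.

    Parameters
    ----------
    df
        Numeric DataFrame indexed by plot id with species ids as columns.
        Values are either binary {0, 1} or percent cover in [0, 100];
        presence is defined as value > 0 in both cases.
    binary
        Declare the table binary; non-{0,1} values then raise.
    """

    df: pd.DataFrame
    binary: bool = True

    def __post_init__(self) -> None:
        _require_unique(self.df.index, "plot")
        _require_unique(self.df.columns, "species")
        values = self.df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("occurrence values must be finite")
        if (values < 0).any():
            raise ValidationError("occurrence values must be >= 0")
        if self.binary:
            if not np.isin(values, (0.0, 1.0)).all():
                raise ValidationError("binary matrix contains values outside {0, 1}")
        elif (values > 100).any():
            raise ValidationError("cover values must lie in [0, 100]")
        self.df = self.df.astype(float).sort_index(axis=0).sort_index(axis=1)
        self.df.index = self.df.index.astype(str)
        self.df.columns = self.df.columns.astype(str)
        self.df.index.name = "plot"
        self.df.columns.name = "species"

    @property
    def plot_ids(self) -> pd.Index:
        return self.df.index

    @property
    def species_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence view: cover > 0 <=> present."""
        return self.df > 0

    def richness(self) -> pd.Series:
        """Observed species richness per plot."""
        return self.presence.sum(axis=1).rename("richness")

    def binarized(self) -> "OccurrenceMatrix":
        return OccurrenceMatrix(self.presence.astype(float), binary=True)

    def subset_plots(self, plot_ids: Sequence[str]) -> "OccurrenceMatrix":
        return OccurrenceMatrix(self.df.loc[list(plot_ids)], binary=self.binary)

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "plot"
        out.to_csv(path)

    @classmethod
    def read(
        cls,
        path: str | Path,
        format: str = "wide",
        value_kind: str = "binary",
    ) -> "OccurrenceMatrix":
        return read_occurrence(path, format=format, value_kind=value_kind)


def read_occurrence(
    path: str | Path, format: str = "wide", value_kind: str = "binary"
) -> OccurrenceMatrix:
    """Read an occurrence table from CSV.

    ``wide`` format has the plot id in the first column and one column per
    species; ``long`` format has columns ``plot,species,value`` and is
    pivoted with absent pairs filled with 0.  Duplicate (plot, species)
    pairs in long input are an error rather than being aggregated silently.
    """
    binary = value_kind == "binary"
    if format == "wide":
        df = pd.read_csv(path, index_col=0)
    elif format == "long":
        long = pd.read_csv(path)
        expected = ["plot", "species", "value"]
        if list(long.columns[:3]) != expected:
            raise ValidationError(f"long occurrence CSV must have columns {expected}")
        dup = long.duplicated(subset=["plot", "species"])
        if dup.any():
            pairs = long.loc[dup, ["plot", "species"]].values.tolist()
            raise ValidationError(f"duplicate (plot, species) pairs in long input: {pairs[:5]}")
        df = long.pivot(index="plot", columns="species", values="value").fillna(0.0)
    else:
        raise ValidationError(f"unknown occurrence format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OccurrenceMatrix(df, binary=binary)


@dataclass
class IndicatorTable:
    """Species x indicator-value table; missing values allowed.

    Indicator values locate a species' realized niche along named
    environmental gradients on a bounded ordinal scale (``value_range``,
    default 1-12 which accommodates both the 1-9 and the 1-12 moisture
    convention).  Species with no value on any dimension are dropped with
    a warning since no envelope decision can be made for them.
    """

    df: pd.DataFrame
    value_range: tuple[float, float] = (1.0, 12.0)

    def __post_init__(self) -> None:
        _require_unique(self.df.index, "species")
        _require_unique(self.df.columns, "indicator dimension")
        values = self.df.to_numpy(dtype=float)
        lo, hi = self.value_range
        finite = np.isfinite(values)
        if ((values[finite] < lo) | (values[finite] > hi)).any():
            raise ValidationError(f"indicator values outside declared range [{lo}, {hi}]")
        all_missing = ~finite.any(axis=1)
        if all_missing.any():
            dropped = self.df.index[all_missing].tolist()
            warnings.warn(
                f"dropping {len(dropped)} species with no indicator value on any dimension"
            )
            self.df = self.df.loc[~all_missing]
        self.df = self.df.astype(float).sort_index(axis=0)
        self.df.index = self.df.index.astype(str)

    @property
    def species_ids(self) -> pd.Index:
        return self.df.index

    @property
    def dims(self) -> list[str]:
        return list(self.df.columns)

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "species"
        out.to_csv(path)

    @classmethod
    def read(cls, path: str | Path, value_range=(1.0, 12.0)) -> "IndicatorTable":
        # indifferent species are coded "x" in the common source tables
        df = pd.read_csv(path, index_col=0, na_values=["x", "X", "~", ""])
        df.index = df.index.astype(str)
        return cls(df.apply(pd.to_numeric, errors="coerce"), value_range=value_range)


@dataclass
class HabitatAssignment:
    """Plot -> habitat mapping (every plot belongs to exactly one habitat)."""

    mapping: pd.Series

    def __post_init__(self) -> None:
        _require_unique(self.mapping.index, "plot")
        if self.mapping.isna().any():
            raise ValidationError("every plot must map to a habitat")
        self.mapping = self.mapping.astype(str).sort_index()
        self.mapping.index = self.mapping.index.astype(str)
        self.mapping.name = "habitat"

    @property
    def plot_ids(self) -> pd.Index:
        return self.mapping.index

    @property
    def habitat_ids(self) -> list[str]:
        return sorted(self.mapping.unique())

    def plots_of(self, habitat: str) -> pd.Index:
        return self.mapping.index[self.mapping == habitat]

    def write(self, path: str | Path) -> None:
        out = self.mapping.rename_axis("plot").reset_index()
        out.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "HabitatAssignment":
        df = pd.read_csv(path, dtype=str)
        return cls(df.set_index("plot")["habitat"])


@dataclass
class EnvTable:
    """Plots x environmental covariates (all finite)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.df.index, "plot")
        _require_unique(self.df.columns, "covariate")
        if not np.isfinite(self.df.to_numpy(dtype=float)).all():
            raise ValidationError("environmental covariates must be finite")
        self.df = self.df.astype(float).sort_index(axis=0)
        self.df.index = self.df.index.astype(str)

    @property
    def plot_ids(self) -> pd.Index:
        return self.df.index

    @property
    def covariates(self) -> list[str]:
        return list(self.df.columns)

    def subset_plots(self, plot_ids: Sequence[str]) -> "EnvTable":
        return EnvTable(self.df.loc[list(plot_ids)])

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "plot"
        out.to_csv(path)

    @classmethod
    def read(cls, path: str | Path) -> "EnvTable":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


@dataclass
class ExpertPoolTable:
    """Habitat -> species affinity lists from expert evaluation.

    Affinity grades form a finite ordinal scale (higher = stronger
    affinity).  The scale is taken from the data — the distinct grades
    observed — rather than hard-coded.
    """

    table: pd.DataFrame  # columns: habitat, species, affinity

    def __post_init__(self) -> None:
        expected = ["habitat", "species", "affinity"]
        if list(self.table.columns[:3]) != expected:
            raise ValidationError(f"expert table must have columns {expected}")
        dup = self.table.duplicated(subset=["habitat", "species"])
        if dup.any():
            raise ValidationError("duplicate species within a habitat in expert table")
        self.table = self.table.copy()
        self.table["habitat"] = self.table["habitat"].astype(str)
        self.table["species"] = self.table["species"].astype(str)
        self.table["affinity"] = pd.to_numeric(self.table["affinity"])
        self.table = self.table.sort_values(["habitat", "species"]).reset_index(drop=True)

    @property
    def grades(self) -> list[float]:
        """The ordinal affinity scale observed in the table, ascending."""
        return sorted(self.table["affinity"].unique())

    @property
    def habitat_ids(self) -> list[str]:
        return sorted(self.table["habitat"].unique())

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ExpertPoolTable":
        return cls(pd.read_csv(path))


def expert_pool(
    table: ExpertPoolTable, include_lowest_affinity: bool = True
) -> dict[str, set[str]]:
    """Per-habitat expert species pools, optionally dropping the weakest grade.

    With ``include_lowest_affinity=False`` species at the minimum grade of
    the observed scale are omitted — these are typically rare species whose
    ecological optimum lies in another habitat.
    """
    grades = table.grades
    if not include_lowest_affinity and len(grades) < 2:
        raise ValidationError("affinity scale needs >= 2 grades to drop the lowest")
    rows = table.table
    if not include_lowest_affinity:
        rows = rows[rows["affinity"] > grades[0]]
    pools: dict[str, set[str]] = {}
    for habitat in table.habitat_ids:
        members = set(rows.loc[rows["habitat"] == habitat, "species"])
        if not members:
            warnings.warn(f"habitat {habitat!r}: empty expert pool after affinity filtering")
        pools[habitat] = members
    return pools


@dataclass
class PoolEstimate:
    """A method's estimate of plot-level species pools.

    ``membership`` is a boolean plots x species DataFrame; ``probability``
    (optional) carries the underlying per-species occurrence probabilities
    in [0, 1].  ``method`` and ``params`` record provenance.
    """

    membership: pd.DataFrame
    probability: pd.DataFrame | None = None
    method: str = ""
    params: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_unique(self.membership.index, "plot")
        _require_unique(self.membership.columns, "species")
        self.membership = self.membership.astype(bool).sort_index(axis=0).sort_index(axis=1)
        self.membership.index = self.membership.index.astype(str)
        self.membership.columns = self.membership.columns.astype(str)
        if self.probability is not None:
            prob = self.probability.sort_index(axis=0).sort_index(axis=1)
            prob.index = prob.index.astype(str)
            prob.columns = prob.columns.astype(str)
            vals = prob.to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any() or not np.isfinite(vals).all():
                raise ValidationError("pool probabilities must lie in [0, 1]")
            if not prob.index.equals(self.membership.index):
                raise ValidationError("probability and membership plot ids differ")
            self.probability = prob

    @property
    def plot_ids(self) -> pd.Index:
        return self.membership.index

    @property
    def species_ids(self) -> pd.Index:
        return self.membership.columns

    def sizes(self) -> pd.Series:
        return self.membership.sum(axis=1).rename("pool_size")

    def write(self, wide_path: str | Path, long_path: str | Path | None = None) -> None:
        wide = self.membership.astype(int)
        wide.index.name = "plot"
        wide.to_csv(wide_path)
        if long_path is not None:
            long = self.membership.stack().rename("member").reset_index()
            long.columns = ["plot", "species", "member"]
            long["member"] = long["member"].astype(int)
            if self.probability is not None:
                prob = self.probability.stack().rename("probability").reset_index()
                long["probability"] = prob["probability"]
            else:
                long["probability"] = np.nan
            long = long[["plot", "species", "probability", "member"]]
            long.to_csv(long_path, index=False)

    @classmethod
    def read(cls, wide_path: str | Path, method: str = "") -> "PoolEstimate":
        df = pd.read_csv(wide_path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df > 0, method=method)


@dataclass
class DarkDiversity:
    """Dark diversity: pool membership minus observed presences."""

    membership: pd.DataFrame
    method: str = ""

    def __post_init__(self) -> None:
        self.membership = self.membership.astype(bool).sort_index(axis=0).sort_index(axis=1)
        self.membership.index = self.membership.index.astype(str)
        self.membership.columns = self.membership.columns.astype(str)

    @property
    def plot_ids(self) -> pd.Index:
        return self.membership.index

    @property
    def species_ids(self) -> pd.Index:
        return self.membership.columns

    @property
    def sizes(self) -> pd.Series:
        return self.membership.sum(axis=1).rename("dark_size")

    def sets(self) -> dict[str, set[str]]:
        """Per-plot dark-diversity species sets."""
        cols = self.membership.columns.to_numpy()
        return {
            plot: set(cols[row.to_numpy()])
            for plot, row in self.membership.iterrows()
        }

    def write(self, path: str | Path) -> None:
        out = self.membership.astype(int)
        out.index.name = "plot"
        out.to_csv(path)

    @classmethod
    def read(cls, path: str | Path, method: str = "") -> "DarkDiversity":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df > 0, method=method)


def dark_from_pool(pool: PoolEstimate, occ: OccurrenceMatrix) -> DarkDiversity:
    """Dark diversity of each plot: species in the estimated pool but not
    recorded in the plot.

    Species universes are aligned by id over their union: species observed
    but absent from the pool estimate are non-members of the dark diversity;
    species in the pool but missing from the occurrence table are treated as
    unobserved everywhere.
    """
    if not pool.plot_ids.isin(occ.plot_ids).all():
        missing = pool.plot_ids.difference(occ.plot_ids).tolist()
        raise ValidationError(f"pool plots missing from occurrence matrix: {missing[:5]}")
    species = pool.species_ids.union(occ.species_ids)
    member = pool.membership.reindex(columns=species, fill_value=False)
    present = (
        occ.presence.reindex(index=pool.plot_ids)
        .reindex(columns=species, fill_value=False)
        .fillna(False)
    )
    return DarkDiversity(member & ~present, method=pool.method)
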