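"""Habitat-level aggregation of plot-level dark diversity.

Plot-level species pools differ within a habitat because of local
heterogeneity; pooling the plot estimates levels this off.  A species is
part of a habitat's dark diversity when it appears in the dark diversity
of at least ``pct_threshold`` percent of that habitat's plots (default 5%,
inclusive).  Raising the threshold can only shrink the habitat pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import DarkDiversity, HabitatAssignment, ValidationError

__all__ = ["HabitatPool", "pool_to_habitat"]


@dataclass
class HabitatPool:
    """Aggregated dark-diversity membership per habitat.

    ``support`` holds, for every habitat x species, the fraction of the
    habitat's plots whose dark diversity contains the species; membership
    is ``support * 100 >= pct_threshold``.
    """

    support: pd.DataFrame  # habitats x species, fractions in [0, 1]
    membership: pd.DataFrame  # habitats x species bool
    pct_threshold: float
    n_plots: pd.Series  # plots per habitat entering the denominator

    @property
    def habitat_ids(self) -> pd.Index:
        return self.support.index

    def sets(self) -> dict[str, set[str]]:
        cols = self.membership.columns.to_numpy()
        return {h: set(cols[row.to_numpy()]) for h, row in self.membership.iterrows()}

    def sizes(self) -> pd.Series:
        return self.membership.sum(axis=1).rename("habitat_dark_size")


def pool_to_habitat(
    dark: DarkDiversity, habitats: HabitatAssignment, pct_threshold: float = 5.0
) -> HabitatPool:
    """Aggregate plot-level dark diversity to habitat membership.

    Only plots present in ``dark`` enter the denominator, so plots whose
    estimate was undefined (e.g. skipped envelope plots) do not dilute the
    support fractions.
    """
    if not (0 < pct_threshold <= 100):
        raise ValidationError("pct_threshold must lie in (0, 100]")
    plots = dark.plot_ids
    unassigned = plots.difference(habitats.plot_ids)
    if len(unassigned):
        raise ValidationError(f"plots without habitat assignment: {list(unassigned)[:5]}")
    groups = habitats.mapping.reindex(plots)
    counts = dark.membership.groupby(groups).sum()
    n_plots = groups.value_counts().sort_index().rename("n_plots")
    if (n_plots == 0).any():
        raise ValidationError("habitat with zero plots")
    support = counts.div(n_plots, axis=0)
    membership = support * 100.0 >= pct_threshold
    return HabitatPool(
        support=support.sort_index(axis=0).sort_index(axis=1),
        membership=membership.sort_index(axis=0).sort_index(axis=1),
        pct_threshold=pct_threshold,
        n_plots=n_plots,
    )
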