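"""Ecological-requirements species-pool estimator (indicator-value envelopes).

For each plot, the mean and standard deviation of the indicator values of
the species recorded there are computed on every dimension (light,
temperature, moisture, soil reaction, nutrients by default).  A candidate
species enters the plot's pool when its standardized distance from the
community mean,

    d = mean over usable dimensions of |x_sd - M_pd| / SD_pd,

does not exceed ``k`` SD units (k of 1.5, 2 or 2.5 are the conventional
envelope widths; larger k admits more species, so pools are nested in k).
Dimensions where the species' value is missing are dropped from the
average; a zero-SD dimension contributes 0 when the species matches the
community value exactly and forces exclusion otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IndicatorTable, OccurrenceMatrix, PoolEstimate, ValidationError

__all__ = ["CommunityEnvelope", "community_envelope", "ellenberg_pool", "ellenberg_estimate"]


@dataclass
class CommunityEnvelope:
    """Per-plot, per-dimension mean/SD of indicator values of present species."""

    mean: pd.DataFrame  # plots x dims
    sd: pd.DataFrame
    n_species: pd.DataFrame  # contributing species per plot x dim
    cover_weighted: bool = False
    sd_divisor: str = "n1"
    skipped_plots: list = field(default_factory=list)

    @property
    def plot_ids(self) -> pd.Index:
        return self.mean.index


def community_envelope(
    occ: OccurrenceMatrix,
    ind: IndicatorTable,
    cover_weighted: bool = False,
    sd_divisor: str = "n1",
) -> CommunityEnvelope:
    """Community mean and SD of indicator values for each plot and dimension.

    Unweighted means use presence/absence; ``cover_weighted`` weights each
    species by its cover.  The unweighted SD uses the sample (n-1) divisor
    by default (``sd_divisor="n"`` switches to the population divisor); the
    cover-weighted SD is the weighted population form.  A dimension with a
    single contributing species gets SD 0 (its count records the fact); a
    plot where no recorded species carries any indicator value is skipped
    with a warning.
    """
    if sd_divisor not in ("n1", "n"):
        raise ValidationError("sd_divisor must be 'n1' or 'n'")
    shared = occ.species_ids.intersection(ind.species_ids)
    weights = (occ.df if cover_weighted else occ.presence.astype(float))[shared].to_numpy()
    values = ind.df.loc[shared].to_numpy()  # (S, D), NaN = missing
    usable = np.isfinite(values)
    V = np.where(usable, values, 0.0)

    n_plots, n_dims = occ.df.shape[0], values.shape[1]
    mean = np.full((n_plots, n_dims), np.nan)
    sd = np.zeros((n_plots, n_dims))
    counts = np.zeros((n_plots, n_dims), dtype=int)
    for d in range(n_dims):
        w = weights * usable[:, d][None, :]
        wsum = w.sum(axis=1)
        counts[:, d] = (w > 0).sum(axis=1)
        ok = wsum > 0
        m = np.where(ok, (w @ V[:, d]) / np.where(ok, wsum, 1.0), np.nan)
        mean[:, d] = m
        ex2 = np.where(ok, (w @ V[:, d] ** 2) / np.where(ok, wsum, 1.0), np.nan)
        var = np.clip(ex2 - m**2, 0.0, None)
        if not cover_weighted and sd_divisor == "n1":
            n = counts[:, d].astype(float)
            var = np.where(n > 1, var * n / np.maximum(n - 1, 1), 0.0)
        sd[:, d] = np.where(ok & (counts[:, d] > 1), np.sqrt(var), 0.0)

    skipped = list(occ.plot_ids[(counts == 0).all(axis=1)])
    if skipped:
        warnings.warn(
            f"{len(skipped)} plots have no species with indicator values; "
            "envelope undefined, plots skipped"
        )
    keep = ~occ.plot_ids.isin(skipped)
    dims = ind.dims
    return CommunityEnvelope(
        mean=pd.DataFrame(mean[keep], index=occ.plot_ids[keep], columns=dims),
        sd=pd.DataFrame(sd[keep], index=occ.plot_ids[keep], columns=dims),
        n_species=pd.DataFrame(counts[keep], index=occ.plot_ids[keep], columns=dims),
        cover_weighted=cover_weighted,
        sd_divisor=sd_divisor,
        skipped_plots=skipped,
    )


def ellenberg_pool(
    envelope: CommunityEnvelope,
    ind: IndicatorTable,
    k: float,
    dim_weights: dict[str, float] | None = None,
) -> PoolEstimate:
    """Admit every species within ``k`` SD units of the community mean.

    The distance is averaged over the dimensions where both the species'
    value and the plot envelope are defined, with equal weight per
    dimension unless ``dim_weights`` overrides it.  Species with no usable
    dimension for a plot are excluded there and flagged.
    """
    if k <= 0:
        raise ValidationError("envelope width k must be positive")
    dims = list(envelope.mean.columns)
    X = ind.df[dims].to_numpy()  # (S, D)
    M = envelope.mean.to_numpy()  # (P, D)
    SD = envelope.sd.to_numpy()
    w = np.array([1.0 if dim_weights is None else dim_weights.get(d, 1.0) for d in dims])
    if (w < 0).any() or w.sum() == 0:
        raise ValidationError("dimension weights must be nonnegative with positive sum")

    n_plots, n_species = M.shape[0], X.shape[0]
    dist_sum = np.zeros((n_plots, n_species))
    weight_sum = np.zeros((n_plots, n_species))
    for d in range(dims.__len__()):
        x = X[:, d]
        usable = np.isfinite(x)[None, :] & np.isfinite(M[:, d])[:, None]
        diff = np.abs(x[None, :] - M[:, d][:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(SD[:, d][:, None] > 0, diff / np.where(SD[:, d][:, None] > 0, SD[:, d][:, None], 1.0), np.where(diff < 1e-9, 0.0, np.inf))
        z = np.where(usable, z, 0.0)
        dist_sum += w[d] * z
        weight_sum += w[d] * usable
    with np.errstate(invalid="ignore"):
        dist = np.where(weight_sum > 0, dist_sum / np.where(weight_sum > 0, weight_sum, 1.0), np.inf)
    member = dist <= k
    no_dim = (weight_sum == 0).all(axis=0)
    return PoolEstimate(
        membership=pd.DataFrame(member, index=envelope.plot_ids, columns=ind.species_ids),
        probability=None,
        method="ellenberg",
        params={
            "k": k,
            "cover_weighted": envelope.cover_weighted,
            "sd_divisor": envelope.sd_divisor,
        },
        flags={
            "skipped_plots": envelope.skipped_plots,
            "no_usable_dimension": list(ind.species_ids[no_dim]),
        },
    )


def ellenberg_estimate(
    occ: OccurrenceMatrix,
    ind: IndicatorTable,
    k: float = 2.0,
    cover_weighted: bool = False,
    sd_divisor: str = "n1",
    dim_weights: dict[str, float] | None = None,
) -> PoolEstimate:
    """Convenience wrapper: envelope then pool in one call."""
    env = community_envelope(occ, ind, cover_weighted=cover_weighted, sd_divisor=sd_divisor)
    return ellenberg_pool(env, ind, k, dim_weights=dim_weights)
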