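"""Co-occurrence species-pool estimator (Beals smoothing).

The index of sociological favourability assigns species *j* in plot *i* the
probability

    b[i, j] = (1 / |S_i \\ {j}|) * sum_{k in S_i, k != j} N_jk / N_k

where ``S_i`` is the set of species recorded in plot *i*, ``N_k`` the number
of reference plots occupied by species *k* and ``N_jk`` the number jointly
occupied by *j* and *k*.  Species that never occur in the reference are
skipped as neighbours (and removed from the denominator count); a plot whose
neighbour set for *j* is empty gets ``b[i, j] = 0``.

Pool membership uses species-specific thresholds: the lowest smoothing value
among the plots where the species is actually recorded, optionally after
discarding low outliers by the Tukey boxplot rule (values below
Q1 - 1.5*IQR).  Without outlier removal the minimum rule guarantees that
every recorded species belongs to its own plot's pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OccurrenceMatrix, PoolEstimate, ValidationError

__all__ = [
    "CooccurrenceCounts",
    "BealsThresholds",
    "cooccurrence_counts",
    "beals_probability",
    "beals_thresholds",
    "beals_pool",
    "beals_estimate",
]


@dataclass
class CooccurrenceCounts:
    """Per-species and joint occurrence counts from a reference dataset."""

    species_ids: pd.Index
    occurrences: np.ndarray  # (S,) int, N_k
    joint: np.ndarray  # (S, S) int, symmetric, diag == occurrences
    n_plots: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.joint, index=self.species_ids, columns=self.species_ids)


def cooccurrence_counts(reference: OccurrenceMatrix) -> CooccurrenceCounts:
    """Exact integer occurrence and joint-occurrence counts over reference plots."""
    if reference.df.shape[0] == 0:
        raise ValidationError("reference dataset has no plots")
    X = reference.presence.to_numpy(dtype=np.int64)
    joint = X.T @ X
    return CooccurrenceCounts(
        species_ids=reference.species_ids,
        occurrences=np.diag(joint).copy(),
        joint=joint,
        n_plots=X.shape[0],
    )


def beals_probability(
    target: OccurrenceMatrix, counts: CooccurrenceCounts
) -> pd.DataFrame:
    """Beals smoothing probabilities for every reference species in every
    target plot.

    The neighbour set of plot *i* is the species recorded there, excluding
    the focal species itself and species with zero reference occurrences.
    Species recorded in the target but unknown to the reference contribute
    nothing as neighbours (they carry zero training frequency).
    """
    species = counts.species_ids
    X = (
        target.presence.reindex(columns=species, fill_value=False)
        .to_numpy(dtype=float)
    )
    N = counts.occurrences.astype(float)
    pos = N > 0
    # M[j, k] = N_jk / N_k where N_k > 0, else 0; M[j, j] = 1 for N_j > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(pos[None, :], counts.joint / np.where(pos, N, 1.0)[None, :], 0.0)
    num = X @ M.T - X * np.diag(M)[None, :]
    den = (X @ pos.astype(float))[:, None] - X * pos[None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return pd.DataFrame(b, index=target.plot_ids, columns=species)


@dataclass
class BealsThresholds:
    """Species-specific pool-inclusion thresholds.

    ``values`` is NaN for species never recorded in the calibration plots —
    such species cannot enter any pool and are listed in ``undefined``.
    """

    values: pd.Series
    outliers_removed: bool
    n_occupied: pd.Series
    undefined: list = field(default_factory=list)


def beals_thresholds(
    prob: pd.DataFrame,
    occ_for_thresholds: OccurrenceMatrix,
    remove_outliers: bool = False,
) -> BealsThresholds:
    """Minimum smoothing value over occupied plots, per species.

    With ``remove_outliers`` the Tukey criterion discards occupied-plot
    values below Q1 - 1.5*IQR (quantiles by linear interpolation) before the
    minimum is taken; if everything would be discarded the plain minimum is
    used.  Removing outliers can only raise a threshold, which shrinks pools.
    """
    pres = occ_for_thresholds.presence.reindex(
        index=prob.index, columns=prob.columns, fill_value=False
    )
    B = prob.to_numpy()
    P = pres.to_numpy(dtype=bool)
    n_occ = P.sum(axis=0)
    thresholds = np.full(B.shape[1], np.nan)
    for j in np.nonzero(n_occ > 0)[0]:
        vals = B[P[:, j], j]
        if remove_outliers and vals.size > 1:
            q1, q3 = np.percentile(vals, [25, 75])
            keep = vals >= q1 - 1.5 * (q3 - q1)
            thresholds[j] = vals[keep].min() if keep.any() else vals.min()
        else:
            thresholds[j] = vals.min()
    undefined = list(prob.columns[n_occ == 0])
    if undefined:
        warnings.warn(
            f"{len(undefined)} species never recorded in threshold-calibration "
            "plots; excluded from pools"
        )
    return BealsThresholds(
        values=pd.Series(thresholds, index=prob.columns, name="threshold"),
        outliers_removed=remove_outliers,
        n_occupied=pd.Series(n_occ, index=prob.columns, name="n_occupied"),
        undefined=undefined,
    )


def beals_pool(prob: pd.DataFrame, thresholds: BealsThresholds) -> PoolEstimate:
    """Threshold the smoothing probabilities into pool membership
    (``b >= threshold``; species without a threshold are members nowhere)."""
    thr = thresholds.values.reindex(prob.columns)
    member = prob.ge(thr, axis=1) & thr.notna()
    return PoolEstimate(
        membership=member,
        probability=prob.clip(0.0, 1.0),
        method="beals",
        params={"remove_outliers": thresholds.outliers_removed},
        flags={"no_threshold": thresholds.undefined},
    )


def beals_estimate(
    train: OccurrenceMatrix | None,
    test: OccurrenceMatrix,
    use_training: bool = True,
    remove_outliers: bool = False,
    threshold_source: str = "test",
) -> PoolEstimate:
    """End-to-end Beals pool estimate for the test plots.

    Co-occurrence counts come from the training plots (``use_training``,
    the default) or from the test plots themselves.  Thresholds are
    calibrated on the plots named by ``threshold_source``.  Species with
    zero occurrences in the reference carry no co-occurrence information
    and are excluded from pools (flagged), as are species never recorded
    in the threshold-calibration plots.
    """
    if use_training:
        if train is None:
            raise ValidationError("use_training requires a training dataset")
        reference = train
    else:
        reference = test
    counts = cooccurrence_counts(reference)
    unseen = counts.species_ids[counts.occurrences == 0].tolist()
    prob = beals_probability(test, counts)
    if unseen:
        warnings.warn(
            f"{len(unseen)} species have zero reference occurrences; excluded from pools"
        )
        prob = prob.drop(columns=unseen)
    if threshold_source == "test":
        thresholds = beals_thresholds(prob, test, remove_outliers)
    elif threshold_source == "train":
        if train is None:
            raise ValidationError("threshold_source='train' requires a training dataset")
        prob_train = beals_probability(train, counts).drop(columns=unseen, errors="ignore")
        thresholds = beals_thresholds(prob_train, train, remove_outliers)
    else:
        raise ValidationError("threshold_source must be 'test' or 'train'")
    pool = beals_pool(prob, thresholds)
    pool.params.update(
        {
            "use_training": use_training,
            "threshold_source": threshold_source,
            "n_reference_plots": counts.n_plots,
        }
    )
    pool.flags["zero_reference_occurrence"] = unseen
    return pool
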