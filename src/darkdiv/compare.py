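"""Congruence statistics between dark-diversity estimates.

Three complementary tests compare a pair of methods:

1. **Size congruence** — Pearson correlation between per-plot dark-diversity
   sizes, plus a standardized major axis (Type II) regression, which treats
   both variables symmetrically; its slope is sign(r) * SD(y)/SD(x), and we
   test slope = 1 and intercept = 0.
2. **Composition overlap** — Simpson overlap |A ∩ B| / min(|A|, |B|)
   between the two dark-diversity sets of each plot, with a
   frequency-weighted null model: random sets of the same size drawn with
   probability proportional to species' training frequencies (999 draws,
   two-tailed test).
3. **Turnover congruence** — Sørensen dissimilarity between the dark
   diversities of all plot pairs within each method (on binary membership
   this coincides with Bray–Curtis), compared across methods with a Mantel
   permutation test (999 permutations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DarkDiversity, ValidationError

__all__ = [
    "SMAFit",
    "OverlapResult",
    "MantelResult",
    "sma_fit",
    "size_congruence",
    "simpson_overlap",
    "overlap_null_test",
    "sorensen_dissimilarity_matrix",
    "mantel_test",
    "compare_report",
]


@dataclass
class SMAFit:
    """Standardized major axis (Type II) regression fit."""

    slope: float
    intercept: float
    r: float
    n: int
    p_slope_eq_1: float
    p_intercept_eq_0: float


def sma_fit(x: Sequence[float], y: Sequence[float]) -> SMAFit:
    """SMA regression of y on x with tests of slope = 1 and intercept = 0.

    The slope is sign(r) * SD(y)/SD(x) exactly; the slope test correlates
    the residual axis (y - x) with the fitted axis (y + x) and refers the
    correlation to a t distribution with n - 2 df; the intercept test is a
    one-sample t on the elevation residuals y - slope * x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValidationError("SMA needs paired samples with n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValidationError("SMA undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())

    # H0 slope = 1: correlation between residual and fitted axes
    res, fit = y - x, y + x
    if res.std() == 0 or fit.std() == 0:
        p_slope = 1.0  # y = x + c exactly: slope indistinguishable from 1
    else:
        r1 = float(np.corrcoef(res, fit)[0, 1])
        r1 = np.clip(r1, -1 + 1e-15, 1 - 1e-15)
        t1 = r1 * np.sqrt((n - 2) / (1 - r1**2))
        p_slope = float(2 * stats.t.sf(abs(t1), n - 2))

    # H0 intercept = 0: one-sample t on elevation residuals
    z = y - slope * x
    if z.std(ddof=1) == 0:
        p_int = 1.0 if abs(z.mean()) < 1e-12 else 0.0
    else:
        t2 = z.mean() / (z.std(ddof=1) / np.sqrt(n))
        p_int = float(2 * stats.t.sf(abs(t2), n - 1))

    return SMAFit(slope=slope, intercept=intercept, r=r, n=n,
                  p_slope_eq_1=p_slope, p_intercept_eq_0=p_int)


def size_congruence(sizes_x: Sequence[float], sizes_y: Sequence[float]) -> dict:
    """Pearson correlation and SMA fit between paired dark-diversity sizes."""
    x = np.asarray(sizes_x, dtype=float)
    y = np.asarray(sizes_y, dtype=float)
    fit = sma_fit(x, y)
    pearson = stats.pearsonr(x, y)
    return {
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "sma": fit,
    }


def simpson_overlap(A: set, B: set) -> float:
    """Simpson (Szymkiewicz–Simpson) overlap: |A ∩ B| / min(|A|, |B|).

    0 when either set is empty (the coefficient is undefined there; callers
    that care can check emptiness themselves).
    """
    if not A or not B:
        return 0.0
    return len(A & B) / min(len(A), len(B))


@dataclass
class OverlapResult:
    """Observed Simpson overlap against the frequency-weighted null."""

    overlap: float
    null_mean: float
    p_value: float
    n_randomizations: int
    empty: bool = False


def _weighted_draws(
    rng: np.random.Generator, weights: np.ndarray, size: int, n_draws: int
) -> np.ndarray:
    """``n_draws`` weighted samples without replacement, as a boolean
    (n_draws x n_species) membership array.

    Uses the Gumbel top-k trick, equivalent to sequential draws with
    probability proportional to weight.
    """
    if size == 0:
        return np.zeros((n_draws, weights.size), dtype=bool)
    logw = np.where(weights > 0, np.log(np.where(weights > 0, weights, 1.0)), -np.inf)
    keys = logw[None, :] + rng.gumbel(size=(n_draws, weights.size))
    top = np.argpartition(-keys, size - 1, axis=1)[:, :size]
    out = np.zeros((n_draws, weights.size), dtype=bool)
    np.put_along_axis(out, top, True, axis=1)
    return out


def overlap_null_test(
    observed: set,
    reference: set,
    freq: pd.Series,
    n_rand: int = 999,
    seed: int | None = None,
) -> OverlapResult:
    """Is the overlap between an estimated set and the reference set larger
    (or smaller) than frequency-matched random sets of the same size?

    Each draw samples |observed| species without replacement with
    probability proportional to their training-set frequency, and the
    Simpson overlap with the reference is recomputed.  The two-tailed
    p-value doubles the smaller tail, with the (r + 1)/(n + 1) inclusion
    convention, capped at 1.
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    if not reference:
        raise ValidationError("reference set is empty")
    freq = freq[freq > 0]
    species = freq.index.to_numpy()
    if not observed:
        return OverlapResult(0.0, 0.0, 1.0, n_rand, empty=True)
    if len(observed) > species.size:
        raise ValidationError("observed set larger than the positive-frequency universe")
    rng = np.random.default_rng(seed)
    obs_overlap = simpson_overlap(observed, reference)

    ref_mask = np.isin(species, list(reference))
    draws = _weighted_draws(rng, freq.to_numpy(dtype=float), len(observed), n_rand)
    inter = draws[:, ref_mask].sum(axis=1)
    null = inter / min(len(observed), len(reference))

    ge = int((null >= obs_overlap - 1e-12).sum())
    le = int((null <= obs_overlap + 1e-12).sum())
    p_up = (ge + 1) / (n_rand + 1)
    p_down = (le + 1) / (n_rand + 1)
    p = min(1.0, 2 * min(p_up, p_down))
    return OverlapResult(
        overlap=obs_overlap,
        null_mean=float(null.mean()),
        p_value=float(p),
        n_randomizations=n_rand,
    )


def sorensen_dissimilarity_matrix(dark: DarkDiversity | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Sørensen dissimilarity d(A,B) = 1 - 2|A∩B|/(|A|+|B|)
    between the plots' dark-diversity sets (0 when both sets are empty)."""
    mem = dark.membership if isinstance(dark, DarkDiversity) else dark
    if mem.shape[0] < 2:
        raise ValidationError("dissimilarity needs >= 2 plots")
    X = mem.to_numpy(dtype=float)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, 1.0 - 2.0 * inter / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=mem.index, columns=mem.index)


@dataclass
class MantelResult:
    """Mantel correlation between two dissimilarity matrices."""

    r: float
    p_value: float
    n_permutations: int


def mantel_test(
    D1: pd.DataFrame | np.ndarray,
    D2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> MantelResult:
    """Mantel test: correlation of the lower triangles, with significance
    from simultaneous row/column permutations of the second matrix
    (one-tailed upper, (r + 1)/(n + 1) convention)."""
    A = np.asarray(D1, dtype=float)
    B = np.asarray(D2, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValidationError("Mantel needs two square matrices of equal shape")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValidationError("Mantel matrices must be symmetric")
    n = A.shape[0]
    iu = np.tril_indices(n, k=-1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("constant lower triangle: Mantel r undefined")
    if method == "spearman":
        a = stats.rankdata(a)

    def _corr(v1, v2):
        if method == "spearman":
            v2 = stats.rankdata(v2)
        v1 = v1 - v1.mean()
        v2 = v2 - v2.mean()
        return float((v1 @ v2) / np.sqrt((v1 @ v1) * (v2 @ v2)))

    r_obs = _corr(a, b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        bp = B[np.ix_(p, p)][iu]
        if _corr(a, bp) >= r_obs - 1e-12:
            count += 1
    p_val = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=float(p_val), n_permutations=n_perm)


def _aligned_sizes(d1: DarkDiversity, d2: DarkDiversity) -> tuple[np.ndarray, np.ndarray]:
    if not d1.plot_ids.equals(d2.plot_ids):
        raise ValidationError("dark-diversity estimates cover different plot sets")
    return d1.sizes.to_numpy(float), d2.sizes.to_numpy(float)


def compare_report(
    methods: Mapping[str, DarkDiversity],
    expert: Mapping[str, set] | None = None,
    freq: pd.Series | None = None,
    n_rand: int = 999,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """All pairwise congruence tests between the named estimates.

    For every method pair: Pearson r and SMA fit of the dark-diversity
    sizes, a paired t-test of the sizes, per-plot Simpson overlaps (with
    the frequency-weighted null test when ``freq`` is given), and the
    Mantel test between the Sørensen dissimilarity structures.  When an
    ``expert`` per-plot reference is given, each method is additionally
    scored against it.  Entries are symmetric in the pair ordering.
    """
    names = sorted(methods)
    if len(names) < 2 and expert is None:
        raise ValidationError("need at least two methods (or one method plus expert)")
    plots = None
    for name in names:
        ids = methods[name].plot_ids
        plots = ids if plots is None else plots
        if not ids.equals(plots):
            raise ValidationError("methods cover different plot universes")

    rng = np.random.default_rng(seed)
    dmats = {name: sorensen_dissimilarity_matrix(methods[name]) for name in names}
    sets = {name: methods[name].sets() for name in names}

    report: dict = {"pairs": {}, "vs_expert": {}}
    for i, m1 in enumerate(names):
        for m2 in names[i + 1:]:
            x, y = _aligned_sizes(methods[m1], methods[m2])
            entry: dict = {}
            entry["size"] = size_congruence(x, y)
            tt = stats.ttest_rel(x, y)
            entry["size"]["paired_t_p"] = float(tt.pvalue)
            overlaps = [
                simpson_overlap(sets[m1][p], sets[m2][p]) for p in plots
            ]
            entry["overlap"] = {
                "mean": float(np.mean(overlaps)),
                "sd": float(np.std(overlaps, ddof=1)) if len(overlaps) > 1 else 0.0,
            }
            mr = mantel_test(
                dmats[m1], dmats[m2], n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            entry["mantel"] = {"r": mr.r, "p": mr.p_value}
            report["pairs"][f"{m1}|{m2}"] = entry

    if expert is not None:
        for name in names:
            entry = {}
            overlaps, pvals = [], []
            for p in plots:
                ref = expert.get(p, set())
                if not ref:
                    continue
                if freq is not None:
                    res = overlap_null_test(
                        sets[name][p], ref, freq, n_rand=n_rand,
                        seed=int(rng.integers(2**31)),
                    )
                    overlaps.append(res.overlap)
                    pvals.append(res.p_value)
                else:
                    overlaps.append(simpson_overlap(sets[name][p], ref))
            entry["overlap_mean"] = float(np.mean(overlaps)) if overlaps else np.nan
            entry["overlap_sd"] = (
                float(np.std(overlaps, ddof=1)) if len(overlaps) > 1 else 0.0
            )
            if pvals:
                entry["pct_significant"] = float(
                    100.0 * np.mean(np.asarray(pvals) <= 0.05)
                )
            report["vs_expert"][name] = entry
    return report
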