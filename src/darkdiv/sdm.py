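"""Species-distribution species-pool estimator.

Each sufficiently frequent species (prevalence filter, default >= 50
occurrences in the training data) gets a logistic regression of its
presence/absence on the environmental covariates, fitted on a random 80%
calibration split.  By default the design includes quadratic terms, so the
fitted occurrence probability can trace the unimodal (niche-shaped)
response expected along environmental gradients.  The probability is
binarized with a species-specific threshold chosen on the held-out 20% by
exhaustive search over the 101-point grid {0.00, 0.01, ..., 1.00},
maximizing either the True Skill Statistic (TSS = sensitivity +
specificity - 1) or Cohen's kappa; both criteria penalize false positives
and false negatives alike.  Target plots whose environmental conditions
pass a species' threshold have that species in their pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .core import EnvTable, OccurrenceMatrix, PoolEstimate, ValidationError

__all__ = [
    "ConfusionSummary",
    "SpeciesModel",
    "prevalence_filter",
    "confusion",
    "tss",
    "kappa",
    "select_threshold",
    "fit_species_model",
    "fit_sdm",
    "sdm_pool",
    "sdm_estimate",
    "covariate_correlations",
]

THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass
class ConfusionSummary:
    """2x2 confusion counts for a binary prediction."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def confusion(observed: np.ndarray, predicted: np.ndarray) -> ConfusionSummary:
    obs = np.asarray(observed, dtype=bool)
    pred = np.asarray(predicted, dtype=bool)
    return ConfusionSummary(
        tp=int((obs & pred).sum()),
        fp=int((~obs & pred).sum()),
        tn=int((~obs & ~pred).sum()),
        fn=int((obs & ~pred).sum()),
    )


def tss(c: ConfusionSummary) -> float:
    """True Skill Statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if c.tp + c.fn == 0:
        raise ValidationError("TSS undefined: no observed presences (TP+FN = 0)")
    if c.tn + c.fp == 0:
        raise ValidationError("TSS undefined: no observed absences (TN+FP = 0)")
    return c.sensitivity + c.specificity - 1.0


def kappa(c: ConfusionSummary) -> float:
    """Cohen's kappa: chance-corrected agreement; 0 when expected agreement is 1."""
    n = c.n
    if n == 0:
        raise ValidationError("kappa undefined: empty confusion table")
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / n**2
    if p_e >= 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def prevalence_filter(occ: OccurrenceMatrix, min_occ: int) -> list[str]:
    """Species recorded in at least ``min_occ`` plots, in stable (sorted) order."""
    if min_occ < 1:
        raise ValidationError("min_occ must be >= 1")
    counts = occ.presence.sum(axis=0)
    return list(counts.index[counts >= min_occ])


def _criterion(name: str):
    if name == "tss":
        return tss
    if name == "kappa":
        return kappa
    raise ValidationError("criterion must be 'tss' or 'kappa'")


def select_threshold(
    prob: np.ndarray, observed: np.ndarray, criterion: str = "tss"
) -> tuple[float, float]:
    """Grid search over the 101-point threshold grid, maximizing the
    criterion; ties broken toward the smallest threshold."""
    score_fn = _criterion(criterion)
    obs = np.asarray(observed, dtype=bool)
    best_t, best_s = None, -np.inf
    for t in THRESHOLD_GRID:
        s = score_fn(confusion(obs, prob >= t))
        if s > best_s:
            best_t, best_s = float(t), float(s)
    return best_t, best_s


@dataclass
class SpeciesModel:
    """Fitted occurrence model and selected threshold for one species."""

    species_id: str
    covariates: list[str]
    coef: np.ndarray  # over the (possibly expanded) design columns
    intercept: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    quadratic: bool
    threshold: float
    criterion: str
    score: float
    n_presences: int
    split_fraction: float
    seed: int
    flags: list[str] = field(default_factory=list)

    def predict_probability(self, env: EnvTable) -> np.ndarray:
        missing = [c for c in self.covariates if c not in env.covariates]
        if missing:
            raise ValidationError(f"missing covariate columns: {missing}")
        Z = _design(env.df[self.covariates].to_numpy(), self.quadratic)
        Z = (Z - self.scale_mean) / self.scale_sd
        eta = Z @ self.coef + self.intercept
        return expit(eta)


def _design(X: np.ndarray, quadratic: bool) -> np.ndarray:
    return np.hstack([X, X**2]) if quadratic else X


def fit_species_model(
    env: EnvTable,
    presence: pd.Series | np.ndarray,
    species_id: str = "",
    split_fraction: float = 0.8,
    criterion: str = "tss",
    seed: int = 0,
    quadratic: bool = True,
    max_split_attempts: int = 20,
) -> SpeciesModel:
    """Fit the logistic occurrence model and pick its binarization threshold.

    The plots are split at random into a calibration fraction (default 80%)
    and a held-out evaluation fraction; the split is redrawn (bounded number
    of attempts) if either class is missing from the calibration part.  The
    threshold maximizes the criterion on the held-out part; if the held-out
    part contains a single class the calibration part is used instead and
    the model is flagged.  Non-converging (e.g. separated) fits fall back to
    an L2-regularized logistic fit, flagged.
    """
    y = np.asarray(presence, dtype=bool).astype(int)
    if y.shape[0] != env.df.shape[0]:
        raise ValidationError("presence vector length does not match env plots")
    if not 0 < split_fraction < 1:
        raise ValidationError("split_fraction must be in (0, 1)")
    _criterion(criterion)  # validate early

    rng = np.random.default_rng(seed)
    n = y.shape[0]
    n_cal = max(int(round(split_fraction * n)), 1)
    flags: list[str] = []
    for attempt in range(max_split_attempts):
        perm = rng.permutation(n)
        cal_idx, out_idx = perm[:n_cal], perm[n_cal:]
        if len(np.unique(y[cal_idx])) == 2:
            break
    else:
        raise ValidationError(
            f"could not obtain both classes in the calibration split for {species_id!r}"
        )

    X = env.df.to_numpy()
    Z = _design(X, quadratic)
    mu = Z[cal_idx].mean(axis=0)
    sd = Z[cal_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Zs = (Z - mu) / sd

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        model.fit(Zs[cal_idx], y[cal_idx])
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged or np.abs(model.coef_).max() > 1e3:
        model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=500)
        model.fit(Zs[cal_idx], y[cal_idx])
        flags.append("ridge_fallback")

    prob = model.predict_proba(Zs)[:, 1]
    if out_idx.size and len(np.unique(y[out_idx])) == 2:
        thr, score = select_threshold(prob[out_idx], y[out_idx], criterion)
    else:
        thr, score = select_threshold(prob[cal_idx], y[cal_idx], criterion)
        flags.append("threshold_on_calibration")

    return SpeciesModel(
        species_id=species_id,
        covariates=env.covariates,
        coef=model.coef_[0].copy(),
        intercept=float(model.intercept_[0]),
        scale_mean=mu,
        scale_sd=sd,
        quadratic=quadratic,
        threshold=thr,
        criterion=criterion,
        score=score,
        n_presences=int(y.sum()),
        split_fraction=split_fraction,
        seed=seed,
        flags=flags,
    )


def fit_sdm(
    train_occ: OccurrenceMatrix,
    train_env: EnvTable,
    min_occ: int = 50,
    split_fraction: float = 0.8,
    criterion: str = "tss",
    seed: int = 0,
    quadratic: bool = True,
) -> dict[str, SpeciesModel]:
    """Fit one model per species passing the prevalence filter.

    Per-species seeds are derived from ``seed`` so the whole fit is
    reproducible and independent of species order.
    """
    if not train_occ.plot_ids.equals(train_env.plot_ids):
        raise ValidationError("training occurrence and env tables must share plots")
    species = prevalence_filter(train_occ, min_occ)
    presence = train_occ.presence
    models: dict[str, SpeciesModel] = {}
    seeds = np.random.SeedSequence(seed).spawn(len(species))
    for sp, ss in zip(species, seeds):
        models[sp] = fit_species_model(
            train_env,
            presence[sp].to_numpy(),
            species_id=sp,
            split_fraction=split_fraction,
            criterion=criterion,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            quadratic=quadratic,
        )
    return models


def sdm_pool(
    models: dict[str, SpeciesModel],
    env_target: EnvTable,
    species_universe: list[str] | None = None,
    common_threshold: pd.Series | None = None,
) -> PoolEstimate:
    """Pool membership of target plots from fitted species models.

    Species without a model (failed the prevalence filter) are members
    nowhere and flagged.  ``common_threshold`` optionally replaces each
    species' own threshold — e.g. with a co-occurrence-style minimum
    threshold — for cross-method threshold experiments.
    """
    species = sorted(species_universe or models.keys())
    prob = pd.DataFrame(0.0, index=env_target.plot_ids, columns=species)
    member = pd.DataFrame(False, index=env_target.plot_ids, columns=species)
    unmodeled = []
    for sp in species:
        if sp not in models:
            unmodeled.append(sp)
            continue
        m = models[sp]
        p = m.predict_probability(env_target)
        thr = m.threshold if common_threshold is None else float(common_threshold[sp])
        prob[sp] = p
        member[sp] = p >= thr
    return PoolEstimate(
        membership=member,
        probability=prob,
        method="sdm",
        params={
            "criterion": next(iter(models.values())).criterion if models else None,
            "common_threshold": common_threshold is not None,
        },
        flags={"unmodeled_species": unmodeled},
    )


def sdm_estimate(
    train_occ: OccurrenceMatrix,
    train_env: EnvTable,
    test_env: EnvTable,
    min_occ: int = 50,
    split_fraction: float = 0.8,
    criterion: str = "tss",
    seed: int = 0,
    quadratic: bool = True,
) -> PoolEstimate:
    """Convenience wrapper: prevalence filter, per-species fits, pool."""
    models = fit_sdm(
        train_occ,
        train_env,
        min_occ=min_occ,
        split_fraction=split_fraction,
        criterion=criterion,
        seed=seed,
        quadratic=quadratic,
    )
    pool = sdm_pool(models, test_env, species_universe=list(train_occ.species_ids))
    pool.params.update({"min_occ": min_occ, "split_fraction": split_fraction, "seed": seed})
    return pool


def covariate_correlations(env: EnvTable) -> pd.DataFrame:
    """Pairwise Pearson correlations between covariates.

    Covariate screening (e.g. keeping a subset with |R| below some bound)
    is a data-preparation decision left to the user; this helper only
    reports the correlation structure.
    """
    return env.df.corr()
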