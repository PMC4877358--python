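"""Seedable synthetic metacommunity with known true species pools.

The generator emulates the statistical structure that the species-pool
estimators assume, so every stage of the pipeline can be exercised against
a known truth:

* plots are placed around habitat centroids in a multi-gradient
  environmental space (default 5 gradients);
* each species has a Gaussian niche on every gradient — suitability of
  species *s* in plot *p* is
  ``h_s * exp(-sum_d (e_pd - mu_sd)^2 / (2 sigma_sd^2))``;
* the *true* species pool of a plot is every species whose suitability
  reaches the cutoff ``tau``;
* occurrence is a Bernoulli draw with probability
  ``suitability * (1 - delta)`` restricted to true-pool members, so the
  dispersal-failure rate ``delta`` (plus suitability thinning) creates the
  true dark diversity;
* indicator values are the niche optima affinely rescaled to the 1–9
  ordinal scale, rounded, with integer-rounded Gaussian noise emulating
  expert imperfection;
* a pseudo-expert habitat table lists species whose mean suitability over
  the habitat's plots reaches ``tau``, graded into affinity terciles.

Defaults correspond to a benchmark with strong niche signal: 300 species,
6 habitats x 40 plots, 5 gradients, 30% dispersal failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    EnvTable,
    ExpertPoolTable,
    HabitatAssignment,
    IndicatorTable,
    OccurrenceMatrix,
    ValidationError,
)

__all__ = ["SimConfig", "SyntheticTruth", "simulate_metacommunity", "split_train_test"]


@dataclass
class SimConfig:
    """Metacommunity generator configuration.

    Niche breadths (``sigma_range``, in gradient units) are broad relative
    to the within-habitat plot scatter (``plot_spread``) and narrow
    relative to the between-habitat centroid spread (``centroid_spread``),
    which makes habitats compositionally distinct while keeping plot-level
    pools well above the suitability cutoff ``tau`` — the "strong niche
    signal" regime.
    """

    n_species: int = 300
    n_habitats: int = 6
    plots_per_habitat: int = 40
    n_gradients: int = 5
    sigma_range: tuple[float, float] = (1.5, 2.5)
    h_range: tuple[float, float] = (0.8, 1.0)
    tau: float = 0.25
    delta: float = 0.3
    indicator_noise_sd: float = 0.5
    centroid_spread: float = 3.0
    plot_spread: float = 0.4
    species_spread: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.delta < 1):
            raise ValidationError("delta must lie in [0, 1)")
        if not (0 < self.tau < 1):
            raise ValidationError("tau must lie in (0, 1)")
        if self.plots_per_habitat < 2:
            raise ValidationError("plots_per_habitat must be >= 2")
        if self.n_species < 1 or self.n_habitats < 1 or self.n_gradients < 1:
            raise ValidationError("counts must be positive")
        for lo, hi, name in (
            (*self.sigma_range, "sigma_range"),
            (*self.h_range, "h_range"),
        ):
            if not (0 < lo <= hi):
                raise ValidationError(f"invalid {name}")
        if self.h_range[1] > 1:
            raise ValidationError("max occurrence probability h must be <= 1")
        if self.indicator_noise_sd < 0:
            raise ValidationError("indicator_noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Generated tables plus the generative truth behind them."""

    config: SimConfig
    niche_optima: np.ndarray  # (S, D)
    niche_breadths: np.ndarray  # (S, D)
    max_prob: np.ndarray  # (S,)
    env_positions: np.ndarray  # (P, D)
    suitability: pd.DataFrame  # plots x species
    true_pool: pd.DataFrame  # plots x species bool
    occurrence: OccurrenceMatrix
    indicators: IndicatorTable
    env: EnvTable
    habitats: HabitatAssignment
    expert: ExpertPoolTable

    def true_dark(self) -> pd.DataFrame:
        """True dark diversity: pool members not drawn as present."""
        return self.true_pool & ~self.occurrence.presence

    def true_habitat_pools(self) -> dict[str, set[str]]:
        """Union of the true plot pools within each habitat."""
        pools: dict[str, set[str]] = {}
        cols = self.true_pool.columns.to_numpy()
        for h in self.habitats.habitat_ids:
            rows = self.true_pool.loc[self.habitats.plots_of(h)]
            pools[h] = set(cols[rows.any(axis=0).to_numpy()])
        return pools


def _plot_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _species_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def simulate_metacommunity(cfg: SimConfig) -> SyntheticTruth:
    """Draw a full synthetic metacommunity; same config -> identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    S, H, D = cfg.n_species, cfg.n_habitats, cfg.n_gradients
    P = H * cfg.plots_per_habitat

    centroids = rng.normal(0.0, cfg.centroid_spread, size=(H, D))
    habitat_of_plot = np.repeat(np.arange(H), cfg.plots_per_habitat)
    env = centroids[habitat_of_plot] + rng.normal(0.0, cfg.plot_spread, size=(P, D))

    # species niches anchor on a random habitat centroid so that every
    # habitat supports a species assemblage
    home = rng.integers(0, H, size=S)
    mu = centroids[home] + rng.normal(0.0, cfg.species_spread, size=(S, D))
    sigma = rng.uniform(*cfg.sigma_range, size=(S, D))
    h = rng.uniform(*cfg.h_range, size=S)

    # suitability(s, p) = h_s * exp(-sum_d (e_pd - mu_sd)^2 / (2 sigma_sd^2))
    z2 = ((env[:, None, :] - mu[None, :, :]) ** 2 / (2.0 * sigma[None, :, :] ** 2)).sum(axis=2)
    suit = h[None, :] * np.exp(-z2)

    true_pool = suit >= cfg.tau
    occ = true_pool & (rng.random(size=suit.shape) < suit * (1.0 - cfg.delta))

    zero_presence = (~occ.any(axis=0)).mean()
    if zero_presence > 0.5:
        raise ValidationError(
            f"{zero_presence:.0%} of species have no presences; widen niches, "
            "raise h, or lower tau"
        )

    plot_ids = _plot_ids(P)
    species_ids = _species_ids(S)
    dims = ["light", "temperature", "moisture", "reaction", "nutrients"][:D] + [
        f"gradient{d + 1}" for d in range(max(0, D - 5))
    ]

    # indicator values: niche optima rescaled per gradient to the 1-9 scale
    lo = env.min(axis=0)
    hi = env.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    iv = 1.0 + 8.0 * (mu - lo[None, :]) / span[None, :]
    iv = np.rint(iv) + np.rint(rng.normal(0.0, cfg.indicator_noise_sd, size=iv.shape))
    iv = np.clip(iv, 1.0, 9.0)

    habitat_ids = [f"H{i + 1}" for i in range(H)]
    habitats = HabitatAssignment(
        pd.Series([habitat_ids[i] for i in habitat_of_plot], index=plot_ids)
    )

    # pseudo-expert table: habitat mean suitability >= tau, graded by terciles
    rows = []
    for hi_idx, hab in enumerate(habitat_ids):
        mean_suit = suit[habitat_of_plot == hi_idx].mean(axis=0)
        members = np.nonzero(mean_suit >= cfg.tau)[0]
        if members.size == 0:
            continue
        vals = mean_suit[members]
        t1, t2 = np.quantile(vals, [1 / 3, 2 / 3])
        grades = 1 + (vals > t1).astype(int) + (vals > t2).astype(int)
        for idx, g in zip(members, grades):
            rows.append((hab, species_ids[idx], int(g)))
    expert = ExpertPoolTable(pd.DataFrame(rows, columns=["habitat", "species", "affinity"]))

    suit_df = pd.DataFrame(suit, index=plot_ids, columns=species_ids)
    return SyntheticTruth(
        config=cfg,
        niche_optima=mu,
        niche_breadths=sigma,
        max_prob=h,
        env_positions=env,
        suitability=suit_df,
        true_pool=pd.DataFrame(true_pool, index=plot_ids, columns=species_ids),
        occurrence=OccurrenceMatrix(
            pd.DataFrame(occ.astype(float), index=plot_ids, columns=species_ids)
        ),
        indicators=IndicatorTable(
            pd.DataFrame(iv, index=species_ids, columns=dims), value_range=(1.0, 9.0)
        ),
        env=EnvTable(pd.DataFrame(env, index=plot_ids, columns=[f"env{d + 1}" for d in range(D)])),
        habitats=habitats,
        expert=expert,
    )


def split_train_test(
    truth: SyntheticTruth, test_plots_per_habitat: int, seed: int = 0
) -> tuple[dict, dict]:
    """Stratified-by-habitat random split into disjoint train/test tables.

    Returns two dicts with keys ``occurrence``, ``env``, ``habitats`` and
    ``plot_ids``.
    """
    rng = np.random.default_rng(seed)
    if test_plots_per_habitat < 1:
        raise ValidationError("test_plots_per_habitat must be >= 1")
    test_plots: list[str] = []
    for h in truth.habitats.habitat_ids:
        plots = list(truth.habitats.plots_of(h))
        if test_plots_per_habitat >= len(plots):
            raise ValidationError(
                f"habitat {h!r}: requested {test_plots_per_habitat} test plots "
                f"of {len(plots)} available"
            )
        test_plots.extend(rng.choice(plots, size=test_plots_per_habitat, replace=False))
    test_plots = sorted(test_plots)
    train_plots = sorted(set(truth.occurrence.plot_ids) - set(test_plots))

    def _tables(plots: list[str]) -> dict:
        return {
            "plot_ids": plots,
            "occurrence": truth.occurrence.subset_plots(plots),
            "env": truth.env.subset_plots(plots),
            "habitats": HabitatAssignment(truth.habitats.mapping.loc[plots]),
        }

    return _tables(train_plots), _tables(test_plots)
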