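# Methods

This note records the models implemented in `darkdiv`, their assumptions,
the numerical choices behind them, and what the synthetic benchmark does
and does not demonstrate.

## Species-pool estimators

### Co-occurrence smoothing

`beals_probability` implements the classical sociological-favourability
index: the probability of species *j* in plot *i* is the average, over the
other species recorded in the plot, of the conditional co-occurrence rates
`N_jk / N_k` computed from a reference dataset. Conventions that the
literature leaves open, fixed here:

* The focal species is excluded from its own plot's neighbour set, but its
  occurrences are **not** subtracted from the reference counts. This is the
  convention of `vegan::beals(type = 0, include = FALSE)`, and the test
  suite verifies machine-precision agreement with vegan. The alternative
  (subtracting the focal species' own occurrences before averaging) exists
  in the literature and would give slightly lower values for occupied
  plots; it is not implemented.
* Reference species with zero occurrences carry no information: they are
  skipped as neighbours, removed from the denominator count, and excluded
  from pools (flagged) rather than entering every pool with a vacuous
  threshold of zero.
* A plot whose neighbour set for a species is empty (e.g. a single-species
  plot) gets probability 0 — no inference is possible, so the conservative
  value is used.

Thresholds are per species: the minimum smoothing value over the plots
where the species is recorded. Without outlier removal this guarantees
**recall 1**: every recorded species is in its own plot's pool, which is
the property that makes the minimum rule self-calibrating. Outlier removal
uses the Tukey boxplot criterion (discard occupied-plot values below
Q1 − 1.5·IQR; quantiles by linear interpolation) and falls back to the
plain minimum if everything would be discarded. Removal can only raise
thresholds, hence only shrink pools — the package asserts this
monotonicity. Thresholds are calibrated by default on the plots being
scored, with an option to calibrate on the training plots instead.

### Indicator-value envelopes

The community envelope is the per-plot, per-dimension mean and SD of the
indicator values of the species present. Choices:

* Sample SD (n − 1 divisor) by default; the population divisor is a flag.
  With many species per plot the difference is negligible; with few it
  widens the envelope slightly, which is the safer direction for a pool
  estimate.
* The species' distance is averaged over the dimensions where both the
  species' value and the envelope are defined, so species with partial
  indicator data are retained rather than dropped. All five dimensions have
  equal weight by default; per-dimension weights are a configuration point.
* A zero-SD dimension (all present species share one value, or a single
  contributor) contributes 0 when the candidate matches that value and
  forces exclusion otherwise. This is the limiting behaviour of the
  standardized distance and avoids dividing by zero.
* "Indifferent" indicator codes (`x`) are mapped to missing at read time.
* The envelope includes all species present in the plot, including the
  candidate itself when it is recorded there.
* Plots where no recorded species carries any indicator value have no
  envelope; they are skipped with a warning and excluded from the habitat
  denominator downstream.

Pools are nested in the envelope width k by construction; the tests assert
the nesting and the monotone growth of mean dark diversity over
k ∈ {1.5, 2, 2.5}.

### Species distribution models

One logistic regression per species on the environmental covariates, with
squared terms appended to the design by default so the log-odds can be
quadratic — the discrete analogue of a Gaussian niche response. A linear
logistic model cannot represent an interior optimum along a gradient, which
is the typical case for realized niches; the quadratic expansion is the
standard GLM practice for this. Covariates are standardized on the
calibration split for optimizer stability; coefficients are stored on that
scale together with the scaling constants.

* Prevalence filter first (default ≥ 50 training occurrences; the
  synthetic benchmark uses 10, scaled to its 180 training plots).
* Random 80/20 calibration/evaluation split per species, seeded; the split
  is redrawn (bounded attempts) if the calibration part lacks a class.
* Threshold by exhaustive search over the 101-point grid
  {0.00, 0.01, …, 1.00}, maximizing TSS or kappa on the held-out part; ties
  break toward the smallest threshold. If the held-out part has a single
  class the calibration part is used and the model flagged. The tests
  verify the selected threshold against an independent sweep for every
  fitted species.
* Separated or non-converging fits fall back to an L2-regularized logistic
  fit, flagged. ROC-based thresholding is not implemented; TSS and kappa
  both already balance false positives against false negatives.
* For cross-method threshold experiments, `sdm_pool` accepts a
  `common_threshold` series that replaces the per-species optimum (e.g.
  with a co-occurrence-style minimum threshold).

The 80/20 split is global per species, drawn once; repeating the split and
averaging thresholds would be a straightforward extension but is not
implemented.

## Dark diversity and habitat aggregation

Dark diversity is pool membership minus observed presence, aligned over the
union of species universes; it is disjoint from the observed community by
construction, and `pool size = richness + dark size` whenever the pool
contains the observed species. Habitat membership uses the fraction of the
habitat's plots whose dark diversity contains the species, with an
inclusive threshold (`support · 100 ≥ pct`, default 5%). Plots with
undefined estimates are excluded from the denominator rather than counted
as absences, so a skipped plot cannot dilute support.

## Comparison statistics

* **SMA regression**: slope is exactly `sign(r) · SD(y)/SD(x)`. The
  slope-equals-1 test correlates the residual axis (y − x) with the fitted
  axis (y + x) and refers the correlation to t with n − 2 df; the
  intercept-equals-0 test is a one-sample t on the elevation residuals
  y − slope·x. The latter ignores the (small) uncertainty in the slope and
  is therefore slightly anti-conservative at small n; at the n of interest
  (hundreds of plots) the approximation is immaterial, and the slope test
  calibrates at the nominal 5% in simulation.
* **Simpson overlap** is size-normalized by the smaller set, so it ignores
  richness differences between estimates; it is 0 (flagged) when either set
  is empty.
* **Overlap null model**: random sets of the observed size drawn without
  replacement with probability proportional to training frequency,
  implemented with the Gumbel top-k trick (equivalent to sequential
  probability-proportional draws, vectorized over all 999 draws).
  Two-tailed p doubles the smaller tail with the (r + 1)/(n + 1) inclusion
  convention, capped at 1. The conditioning size is the dark-diversity set
  size of the plot, consistent with all comparisons being made on dark
  diversity. Because the overlap statistic is discrete, the doubled-tail
  test is mildly conservative; calibration simulations land near 4% at a
  nominal 5%.
* **Sørensen dissimilarity** on binary membership (where it coincides with
  Bray–Curtis) between all plot pairs; pairs of empty sets get distance 0,
  flagged by construction.
* **Mantel test**: Pearson correlation of lower triangles (Spearman as an
  option), one-tailed upper p from simultaneous row/column permutations.
* Paired t-tests of sizes are reported descriptively, without
  multiple-testing correction.

## Synthetic metacommunity

The generator creates the structure the estimators assume, nothing more:
habitat centroids in a D-dimensional gradient space (spread 3.0), plots
scattered around them (SD 0.4), species niche optima anchored on a random
habitat's centroid (SD 0.6) with Gaussian niche breadths drawn from
1.5–2.5 gradient units and maximum occurrence probability 0.8–1.0. The
true pool is suitability ≥ τ = 0.25; occurrence is Bernoulli
(suitability · (1 − δ)) restricted to pool members with dispersal-failure
rate δ = 0.3. These defaults put habitats far enough apart that pools are
habitat-specific while within-habitat suitability stays high — the
strong-niche-signal regime — and give realistic plot richness (~25
species) at the default size of 300 species and 6 habitats × 40 plots.
The identity `E[dark fraction of pool] = 1 − (1 − δ) · mean pool
suitability` is checked in the tests at δ = 0 and δ = 0.3.

Indicator values are the niche optima rescaled per gradient to 1–9,
rounded, plus integer-rounded Gaussian noise (SD 0.5) emulating expert
imperfection. The pseudo-expert table lists, per habitat, species whose
mean suitability over the habitat's plots reaches τ, graded into affinity
terciles (1–3).

What the generator does **not** emulate: spatially explicit dispersal,
species interactions, abundance structure beyond presence (covers are not
simulated), sampling error in the plots, non-Gaussian or asymmetric
niches, and correlated gradients. Passing the benchmark therefore shows
that each estimator recovers pools when its own assumptions hold and when
co-occurrence, indicator and environmental signals are all strong and
mutually consistent; it does not bound performance on real vegetation
data, where the three signals can disagree.

## Benchmark sizes and tolerances

The test suite runs the benchmark at 300 species, 6 habitats × 40 plots
with a 10-plots-per-habitat test split; oracle-equivalence checks use 200
random 20 × 15 matrices at 1e-12; the permutation-test calibrations use
1000 replicates of 999 draws/permutations and accept 5% ± 1.5% rejection
(binomial Monte-Carlo tolerance). The acceptance script reports the same
quantities at 500 calibration replicates. All random streams are derived
from a single seed; reruns are byte-identical, which the provenance
manifest (SHA-256 per artifact) makes checkable.

## Known limitations

* The Beals convention question (whether to subtract the focal species'
  own occurrences from the counts) is resolved by matching vegan's
  `include = FALSE`; data built under the other convention will differ
  most for rare species.
* The indicator-value estimator treats dimensions as independent; strongly
  correlated indicator dimensions effectively double-count.
* Only the logistic probability model is built in; the `SpeciesModel`
  contract (probability + threshold) is the seam for plugging other
  learners.
* Habitat-level pools are unions over plot evidence; no between-habitat
  smoothing is attempted.
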