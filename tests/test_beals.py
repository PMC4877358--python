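import numpy as np
import pandas as pd
import pytest

import darkdiv as dd
from darkdiv.core import ValidationError

from conftest import random_occurrence


def naive_beals(target, counts):
    """Brute-force double-loop recomputation of the smoothing index."""
    species = list(counts.species_ids)
    N = dict(zip(species, counts.occurrences))
    J = {
        (a, b): counts.joint[i, j]
        for i, a in enumerate(species)
        for j, b in enumerate(species)
    }
    out = pd.DataFrame(0.0, index=target.plot_ids, columns=species)
    pres = target.presence
    for plot in target.plot_ids:
        S_i = [s for s in species if s in pres.columns and pres.loc[plot, s]]
        for j in species:
            neighbors = [k for k in S_i if k != j and N[k] > 0]
            if neighbors:
                out.loc[plot, j] = sum(J[(j, k)] / N[k] for k in neighbors) / len(neighbors)
    return out


class TestCooccurrenceCounts:
    def test_hand_counts(self, toy_occurrence):
        c = dd.cooccurrence_counts(toy_occurrence)
        assert c.occurrences.tolist() == [2, 2, 2]
        assert c.joint[0, 1] == c.joint[0, 2] == c.joint[1, 2] == 1
        assert (np.diag(c.joint) == c.occurrences).all()

    def test_single_plot_single_species(self):
        occ = dd.OccurrenceMatrix(pd.DataFrame([[1.0]], index=["P1"], columns=["A"]))
        c = dd.cooccurrence_counts(occ)
        assert c.occurrences.tolist() == [1]

    def test_duplicated_plots_double_counts(self, toy_occurrence):
        doubled = dd.OccurrenceMatrix(
            pd.concat(
                [toy_occurrence.df, toy_occurrence.df.set_axis(["Q1", "Q2", "Q3"])]
            )
        )
        c1 = dd.cooccurrence_counts(toy_occurrence)
        c2 = dd.cooccurrence_counts(doubled)
        assert (c2.joint == 2 * c1.joint).all()

    def test_joint_bounded_by_marginals(self):
        rng = np.random.default_rng(0)
        occ = random_occurrence(rng)
        c = dd.cooccurrence_counts(occ)
        bound = np.minimum(c.occurrences[:, None], c.occurrences[None, :])
        assert (c.joint <= bound).all()
        assert (c.joint == c.joint.T).all()


class TestBealsProbability:
    def test_hand_example(self, toy_occurrence):
        counts = dd.cooccurrence_counts(toy_occurrence)
        b = dd.beals_probability(toy_occurrence, counts)
        # A at P3 = {B, C}: (N_AB/N_B + N_AC/N_C)/2 = (1/2 + 1/2)/2 = 0.5
        assert b.loc["P3", "A"] == pytest.approx(0.5)
        # A at P1 = {A, B}: neighbour set {B} only -> N_AB/N_B = 0.5
        assert b.loc["P1", "A"] == pytest.approx(0.5)

    def test_lone_species_plot_gets_zero(self):
        occ = dd.OccurrenceMatrix(
            pd.DataFrame([[1.0, 0.0], [1.0, 1.0]], index=["P1", "P2"], columns=["A", "B"])
        )
        b = dd.beals_probability(occ, dd.cooccurrence_counts(occ))
        assert b.loc["P1", "A"] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reference = random_occurrence(rng)
        target = random_occurrence(rng, n_plots=10)
        counts = dd.cooccurrence_counts(reference)
        fast = dd.beals_probability(target, counts)
        slow = naive_beals(target, counts)
        assert np.abs(fast.to_numpy() - slow.to_numpy()).max() < 1e-12

    def test_probabilities_bounded(self):
        rng = np.random.default_rng(11)
        occ = random_occurrence(rng, n_plots=30, p=0.5)
        b = dd.beals_probability(occ, dd.cooccurrence_counts(occ))
        assert (b.to_numpy() >= 0).all() and (b.to_numpy() <= 1).all()

    def test_unity_when_neighbours_always_joint(self):
        # A always co-occurs with B, so N_AB = N_B and b(A | {B}) = 1
        occ = dd.OccurrenceMatrix(
            pd.DataFrame(
                [[1, 1], [1, 1], [1, 1]],
                index=["P1", "P2", "P3"],
                columns=["A", "B"],
                dtype=float,
            )
        )
        b = dd.beals_probability(occ, dd.cooccurrence_counts(occ))
        assert b.loc["P1", "A"] == pytest.approx(1.0)


class TestThresholds:
    def test_minimum_over_occupied_plots(self, toy_occurrence):
        counts = dd.cooccurrence_counts(toy_occurrence)
        b = dd.beals_probability(toy_occurrence, counts)
        thr = dd.beals_thresholds(b, toy_occurrence)
        assert thr.values["A"] == pytest.approx(0.5)

    def test_tukey_outlier_removal(self):
        vals = np.array([0.50, 0.52, 0.54, 0.56, 0.02])
        prob = pd.DataFrame({"A": vals}, index=[f"P{i}" for i in range(5)])
        occ = dd.OccurrenceMatrix(
            pd.DataFrame({"A": np.ones(5)}, index=[f"P{i}" for i in range(5)])
        )
        plain = dd.beals_thresholds(prob, occ, remove_outliers=False)
        cleaned = dd.beals_thresholds(prob, occ, remove_outliers=True)
        assert plain.values["A"] == pytest.approx(0.02)
        assert cleaned.values["A"] == pytest.approx(0.50)

    def test_single_occupied_plot_removal_noop(self):
        prob = pd.DataFrame({"A": [0.3]}, index=["P1"])
        occ = dd.OccurrenceMatrix(pd.DataFrame({"A": [1.0]}, index=["P1"]))
        for flag in (False, True):
            thr = dd.beals_thresholds(prob, occ, remove_outliers=flag)
            assert thr.values["A"] == pytest.approx(0.3)

    def test_never_occupied_species_has_no_threshold(self):
        prob = pd.DataFrame({"A": [0.3], "B": [0.4]}, index=["P1"])
        occ = dd.OccurrenceMatrix(
            pd.DataFrame({"A": [1.0], "B": [0.0]}, index=["P1"])
        )
        with pytest.warns(UserWarning, match="never recorded"):
            thr = dd.beals_thresholds(prob, occ)
        assert np.isnan(thr.values["B"])
        assert thr.undefined == ["B"]
        pool = dd.beals_pool(prob, thr)
        assert not pool.membership["B"].any()

    @pytest.mark.parametrize("seed", range(5))
    def test_outlier_removal_never_lowers_threshold(self, seed):
        rng = np.random.default_rng(seed)
        occ = random_occurrence(rng, n_plots=30, p=0.4)
        b = dd.beals_probability(occ, dd.cooccurrence_counts(occ))
        t0 = dd.beals_thresholds(b, occ, remove_outliers=False).values
        t1 = dd.beals_thresholds(b, occ, remove_outliers=True).values
        assert (t1 >= t0 - 1e-15).all()


class TestBealsEstimate:
    @pytest.mark.parametrize("seed", range(5))
    def test_recall_of_recorded_species(self, seed):
        """Minimum-rule thresholds put every recorded species in its own pool."""
        rng = np.random.default_rng(seed)
        occ = random_occurrence(rng, n_plots=25, p=0.35)
        pool = dd.beals_estimate(None, occ, use_training=False, remove_outliers=False)
        present = occ.presence[pool.membership.columns]
        assert (pool.membership | ~present).all().all()

    def test_outlier_removal_shrinks_pools(self, benchmark):
        train, test = benchmark["train"], benchmark["test"]
        plain = dd.beals_estimate(train["occurrence"], test["occurrence"])
        cleaned = dd.beals_estimate(
            train["occurrence"], test["occurrence"], remove_outliers=True
        )
        assert cleaned.sizes().mean() < plain.sizes().mean()
        # membership is nested, not merely smaller
        assert (cleaned.membership <= plain.membership).all().all()

    def test_reference_size_preserves_bounds_and_recall(self, benchmark):
        train, test = benchmark["train"], benchmark["test"]
        pool = dd.beals_estimate(train["occurrence"], test["occurrence"])
        prob = pool.probability.to_numpy()
        assert (prob >= 0).all() and (prob <= 1).all()
        present = test["occurrence"].presence[pool.membership.columns]
        assert (pool.membership | ~present).all().all()

    def test_threshold_source_train(self, benchmark):
        train, test = benchmark["train"], benchmark["test"]
        pool = dd.beals_estimate(
            train["occurrence"], test["occurrence"], threshold_source="train"
        )
        assert pool.params["threshold_source"] == "train"
        assert pool.sizes().mean() > 0

    def test_requires_training_when_requested(self, toy_occurrence):
        with pytest.raises(ValidationError, match="training"):
            dd.beals_estimate(None, toy_occurrence, use_training=True)
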