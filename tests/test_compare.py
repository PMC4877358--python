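import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import darkdiv as dd
from darkdiv.core import DarkDiversity, ValidationError


class TestSMA:
    @pytest.mark.parametrize("seed", range(5))
    def test_slope_formula_exact(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        fit = dd.sma_fit(x, y)
        r = np.corrcoef(x, y)[0, 1]
        expected = np.sign(r) * y.std(ddof=1) / x.std(ddof=1)
        assert fit.slope == expected  # exact, not approximate

    def test_identity_line(self):
        x = np.arange(30.0)
        fit = dd.sma_fit(x, x.copy())
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)
        assert fit.p_slope_eq_1 > 0.05
        assert fit.p_intercept_eq_0 > 0.05

    def test_doubled_slope_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        fit = dd.sma_fit(x, 2.0 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.p_slope_eq_1 < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            dd.sma_fit(np.ones(10), np.arange(10.0))

    def test_slope_test_near_nominal_level(self):
        """Under H0 (true SMA slope 1, symmetric noise) the slope test
        rejects at about the nominal 5%."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            if dd.sma_fit(x, y).p_slope_eq_1 <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09


class TestSimpsonOverlap:
    def test_basic_arithmetic(self):
        assert dd.simpson_overlap({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)

    def test_subset_gives_one(self):
        assert dd.simpson_overlap({"a"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_and_empty(self):
        assert dd.simpson_overlap({"a"}, {"b"}) == 0.0
        assert dd.simpson_overlap(set(), {"b"}) == 0.0

    def test_invariant_to_enlarging_bigger_set(self):
        A = {"a", "b"}
        B = {"a", "c", "d"}
        base = dd.simpson_overlap(A, B)
        assert dd.simpson_overlap(A, B | {"e", "f", "g"}) == base


class TestOverlapNull:
    def _freq(self, n=100):
        return pd.Series(1.0, index=[f"S{i:03d}" for i in range(n)])

    def test_identical_sets_significant(self):
        freq = self._freq()
        obs = set(freq.index[:5])
        res = dd.overlap_null_test(obs, obs, freq, n_rand=999, seed=0)
        assert res.overlap == 1.0
        assert res.p_value <= 0.05

    def test_zero_randomizations_rejected(self):
        freq = self._freq()
        with pytest.raises(ValidationError):
            dd.overlap_null_test({"S000"}, {"S001"}, freq, n_rand=0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            dd.overlap_null_test({"S000"}, set(), self._freq())

    def test_weighted_draws_favour_frequent_species(self):
        freq = self._freq()
        freq.iloc[:10] = 100.0  # ten dominant species
        res = dd.overlap_null_test(
            set(freq.index[:10]), set(freq.index[:10]), freq, n_rand=500, seed=1
        )
        # the null itself now often picks the dominant species
        assert res.null_mean > 0.5


class TestSorensen:
    def test_hand_values(self):
        mem = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], index=["P1", "P2"], columns=["a", "b", "c"]
        ).astype(bool)
        D = dd.sorensen_dissimilarity_matrix(DarkDiversity(mem))
        assert D.loc["P1", "P2"] == pytest.approx(0.5)
        assert D.loc["P1", "P1"] == 0.0

    def test_identical_and_disjoint(self):
        mem = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["P1", "P2", "P3"],
            columns=list("abcd"),
        ).astype(bool)
        D = dd.sorensen_dissimilarity_matrix(DarkDiversity(mem))
        assert D.loc["P1", "P2"] == 0.0
        assert D.loc["P1", "P3"] == 1.0
        assert np.allclose(D, D.T)

    def test_both_empty_sets_give_zero(self):
        mem = pd.DataFrame(
            [[0, 0], [0, 0]], index=["P1", "P2"], columns=["a", "b"]
        ).astype(bool)
        D = dd.sorensen_dissimilarity_matrix(DarkDiversity(mem))
        assert D.loc["P1", "P2"] == 0.0


class TestMantel:
    def _dist(self, rng, n=15):
        return squareform(pdist(rng.normal(size=(n, 3))))

    def test_identity_gives_r_one_min_p(self):
        rng = np.random.default_rng(5)
        D = self._dist(rng)
        res = dd.mantel_test(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_r_matches_lower_triangle_correlation(self):
        rng = np.random.default_rng(6)
        D1, D2 = self._dist(rng), self._dist(rng)
        res = dd.mantel_test(D1, D2, n_perm=9, seed=0)
        iu = np.tril_indices(D1.shape[0], k=-1)
        direct = np.corrcoef(D1[iu], D2[iu])[0, 1]
        assert abs(res.r - direct) < 1e-12

    def test_constant_triangle_rejected(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValidationError, match="constant"):
            dd.mantel_test(D, D, n_perm=9)

    def test_asymmetric_matrix_rejected(self):
        D = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValidationError, match="symmetric"):
            dd.mantel_test(D, D, n_perm=9)

    def test_spearman_option(self):
        rng = np.random.default_rng(7)
        D = self._dist(rng)
        res = dd.mantel_test(D, D**2, n_perm=99, seed=0, method="spearman")
        assert res.r == pytest.approx(1.0)  # monotone transform


class TestCompareReport:
    def test_identical_estimates_fully_congruent(self, benchmark):
        d = benchmark["darks"]["beals"]
        report = dd.compare_report(
            {"m1": d, "m2": DarkDiversity(d.membership.copy())},
            n_rand=99, n_perm=99, seed=0,
        )
        entry = report["pairs"]["m1|m2"]
        assert entry["size"]["pearson_r"] == pytest.approx(1.0)
        assert entry["overlap"]["mean"] == pytest.approx(1.0)
        assert entry["mantel"]["r"] == pytest.approx(1.0)

    def test_report_symmetric_in_method_order(self, benchmark):
        darks = benchmark["darks"]
        r1 = dd.compare_report(darks, n_perm=49, seed=0)
        r2 = dd.compare_report(dict(reversed(list(darks.items()))), n_perm=49, seed=0)
        assert set(r1["pairs"]) == set(r2["pairs"])
        for key in r1["pairs"]:
            assert r1["pairs"][key]["size"]["pearson_r"] == pytest.approx(
                r2["pairs"][key]["size"]["pearson_r"]
            )

    def test_expert_reference_scored(self, benchmark):
        truth, test = benchmark["truth"], benchmark["test"]
        expert_sets = dd.expert_pool(truth.expert)
        observed = test["occurrence"].presence
        cols = observed.columns.to_numpy()
        expert_dark = {
            p: expert_sets[truth.habitats.mapping[p]]
            - set(cols[observed.loc[p].to_numpy()])
            for p in observed.index
        }
        freq = benchmark["train"]["occurrence"].presence.sum(0)
        report = dd.compare_report(
            {k: benchmark["darks"][k] for k in ("beals", "ellenberg")},
            expert=expert_dark, freq=freq, n_rand=99, n_perm=49, seed=0,
        )
        for name in ("beals", "ellenberg"):
            entry = report["vs_expert"][name]
            assert 0.0 < entry["overlap_mean"] <= 1.0
            assert 0.0 <= entry["pct_significant"] <= 100.0

    def test_mismatched_plot_universes_rejected(self, benchmark):
        d = benchmark["darks"]["beals"]
        other = DarkDiversity(d.membership.iloc[:-1])
        with pytest.raises(ValidationError, match="plot"):
            dd.compare_report({"m1": d, "m2": other})
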