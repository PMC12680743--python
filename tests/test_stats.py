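"""Rank statistics against scipy and formula oracles; letter-display logic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from modcomm.stats import (compact_letter_display, dunn_bonferroni,
                           kruskal_wallis, shapiro_screen, spearman,
                           wilcoxon_rank_sum)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_smallest_attainable_p_for_three_vs_three(self):
        # fully separated samples: the extreme tail has 1/20 of the 20 rank
        # assignments, so the two-sided exact p is 0.1
        res = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1)
        assert res.extra["exact"]

    def test_symmetry_in_sample_order(self):
        x, y = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            wilcoxon_rank_sum(y, x).p_value)

    def test_exact_matches_scipy_mannwhitney(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 8))
            y = rng.normal(size=rng.integers(3, 8))
            ours = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(0.4, 1.0, size=25)
            ours = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_pooled_sample_flagged(self):
        res = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0
        assert res.extra["zero_variance"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(size=15)
        p1 = wilcoxon_rank_sum(x, y).p_value
        p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y)).p_value
        assert p1 == pytest.approx(p2)


class TestKruskalWallis:
    def test_all_equal_gives_zero_h(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0], [5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_rank_formula(self):
        # groups (1,2),(3,4),(5,6): ranks are the values themselves
        # H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7 = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [np.round(rng.normal(size=rng.integers(3, 12)), 1)
                      for _ in range(rng.integers(2, 5))]
            ours = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_group_relabeling_leaves_h_unchanged(self):
        groups = [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis(list(reversed(groups))).statistic
        assert h1 == pytest.approx(h2)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestDunn:
    def test_z_matches_published_formula_without_ties(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        res = dunn_bonferroni(groups, labels=["a", "b", "c"])
        # mean ranks 2, 5, 8; pooled variance term N(N+1)/12 = 7.5
        se = np.sqrt(7.5 * (1 / 3 + 1 / 3))
        z_ab = (2 - 5) / se
        row = res.set_index(["group_1", "group_2"])
        assert row.loc[("a", "b"), "z"] == pytest.approx(z_ab)
        assert row.loc[("a", "c"), "z"] == pytest.approx((2 - 8) / se)
        expect_p = min(1.0, 3 * 2 * sps.norm.sf(abs(z_ab)))
        assert row.loc[("a", "b"), "p_adj"] == pytest.approx(expect_p)

    def test_bonferroni_factor_is_number_of_pairs(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=10) for _ in range(4)]
        res = dunn_bonferroni(groups)
        expect = np.minimum(1.0, res["p_raw"] * 6)  # 4 groups -> 6 pairs
        assert np.allclose(res["p_adj"], expect)
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
        assert (res["p_adj"] <= 1.0).all()

    def test_identical_groups_have_adjusted_p_one(self):
        same = [10.0, 20.0, 30.0]
        res = dunn_bonferroni([same, same, [100.0, 200.0, 300.0]],
                              labels=["a", "b", "c"])
        row = res.set_index(["group_1", "group_2"])
        assert row.loc[("a", "b"), "p_adj"] == 1.0

    def test_tie_correction_applied(self):
        # heavy ties shrink the variance term relative to the tie-free value
        groups = [[1, 1, 2], [2, 2, 3], [3, 3, 1]]
        res = dunn_bonferroni(groups)
        assert res["p_adj"].between(0, 1).all()


class TestCompactLetterDisplay:
    def _pmat(self, labels, sig_pairs):
        m = pd.DataFrame(1.0, index=labels, columns=labels)
        for a, b in sig_pairs:
            m.loc[a, b] = m.loc[b, a] = 0.001
        return m

    def test_intermediate_group_shares_both_letters(self):
        letters = compact_letter_display(
            self._pmat(["A", "B", "C"], [("A", "B")]))
        assert letters == {"A": "a", "B": "b", "C": "ab"}

    def test_no_significant_pairs_single_letter(self):
        letters = compact_letter_display(self._pmat(["A", "B", "C"], []))
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        letters = compact_letter_display(
            self._pmat(["A", "B", "C"], [("A", "B"), ("A", "C"), ("B", "C")]))
        assert letters == {"A": "a", "B": "b", "C": "c"}

    def test_missing_pair_errors(self):
        m = self._pmat(["A", "B"], [])
        m.loc["A", "B"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            compact_letter_display(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_invariant_on_random_patterns(self, seed):
        # groups share a letter exactly when not significantly different
        rng = np.random.default_rng(seed)
        labels = [f"g{i}" for i in range(rng.integers(2, 7))]
        sig = [(a, b) for a, b in itertools.combinations(labels, 2)
               if rng.random() < 0.4]
        letters = compact_letter_display(self._pmat(labels, sig))
        sig_set = {frozenset(p) for p in sig}
        for a, b in itertools.combinations(labels, 2):
            shares = bool(set(letters[a]) & set(letters[b]))
            assert shares != (frozenset((a, b)) in sig_set), (letters, sig)


class TestSpearman:
    def test_perfect_monotone_and_reversal(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 4.0, 10.0, 20.0])[0] == pytest.approx(1.0)
        assert spearman(x, [-1.0, -2.0, -3.0, -4.0])[0] == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0]
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_matches_midrank_formula(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0]
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expect = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expect)

    def test_constant_input_flagged_nan(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [3.0, 4.0])


class TestShapiro:
    def test_uniform_sample_flagged_nonnormal(self):
        rng = np.random.default_rng(5)
        res = shapiro_screen(rng.uniform(size=500))
        assert res.extra["nonnormal"]

    def test_gaussian_sample_usually_passes(self):
        rng = np.random.default_rng(6)
        res = shapiro_screen(rng.normal(size=200))
        assert res.p_value > 0.05

    def test_affine_invariance_of_w(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        assert shapiro_screen(x).statistic == pytest.approx(
            shapiro_screen(5.0 + 3.0 * x).statistic)

    def test_tiny_or_constant_samples_error(self):
        with pytest.raises(ValueError):
            shapiro_screen([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_screen([1.0] * 10)
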