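"""Relative abundance, growth categories and accumulation curves."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from modcomm import ecology
from modcomm.io_formats import CoverageTable


def _coverage(values, mean_cov):
    cov = pd.DataFrame(values)
    return CoverageTable(cov, pd.Series(mean_cov, index=cov.columns))


class TestRelativeAbundance:
    def test_printed_formula(self):
        table = _coverage({"s1": {"g1": 10.0}}, {"s1": 50.0})
        prof = ecology.relative_abundance(table)
        assert prof.loc["g1", "ra_s1"] == pytest.approx(0.2)

    def test_prevalence_counts_nonzero_samples(self):
        table = _coverage(
            {"s1": {"g1": 0.0}, "s2": {"g1": 5.0},
             "s3": {"g1": 15.0}, "s4": {"g1": 0.0}},
            {"s1": 50.0, "s2": 50.0, "s3": 50.0, "s4": 50.0})
        prof = ecology.relative_abundance(table)
        assert prof.loc["g1", "prevalence"] == 0.5

    def test_all_zero_genome(self):
        table = _coverage({"s1": {"g1": 0.0, "g2": 4.0},
                           "s2": {"g1": 0.0, "g2": 2.0}},
                          {"s1": 40.0, "s2": 20.0})
        prof = ecology.relative_abundance(table)
        assert prof.loc["g1", "mean_relative_abundance"] == 0.0
        assert prof.loc["g1", "prevalence"] == 0.0

    def test_ra_times_mean_coverage_recovers_coverage(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(rng.uniform(0, 30, (5, 4)),
                           index=[f"g{i}" for i in range(5)],
                           columns=[f"s{j}" for j in range(4)])
        table = CoverageTable(cov, pd.Series([55.0, 44.0, 33.0, 22.0],
                                             index=cov.columns))
        prof = ecology.relative_abundance(table)
        ra = prof[[f"ra_s{j}" for j in range(4)]].to_numpy()
        back = ra * table.mean_coverage.to_numpy()[None, :]
        assert np.allclose(back, table.coverage.to_numpy())


class TestComplexity:
    @pytest.mark.parametrize("n,expect", [
        (1, "1"), (2, "2"), (3, "3"), (4, "gt3"), (13, "gt3")])
    def test_class_by_member_count(self, n, expect):
        assert ecology.complexity_class(n) == expect

    def test_zero_members_invalid(self):
        with pytest.raises(ValueError):
            ecology.complexity_class(0)

    def test_classes_from_membership_table(self):
        cultures = pd.DataFrame({
            "culture_id": ["a", "b", "b", "c", "c", "c", "c"],
            "species_id": ["x", "x", "y", "p", "q", "r", "s"]})
        cls = ecology.complexity_classes(cultures)
        assert cls.to_dict() == {"a": "1", "b": "2", "c": "gt3"}


class TestGrowthCategories:
    def _table(self, memberships):
        rows = [(c, s) for c, members in memberships.items() for s in members]
        return pd.DataFrame(rows, columns=["culture_id", "species_id"])

    def test_single_group_and_both(self):
        cultures = self._table({
            "c1": ["solo"], "c2": ["solo"],
            "c3": ["grp", "other"], "c4": ["grp", "other", "third"],
            "c5": ["flex"], "c6": ["flex", "grp", "third"],
        })
        cats = ecology.classify_growth(cultures)
        assert cats.loc["solo", "category"] == "Single"
        assert cats.loc["grp", "category"] == "Group"
        assert cats.loc["flex", "category"] == "Both"
        assert bool(cats.loc["flex", "singleton_capable"])
        assert bool(cats.loc["solo", "singleton_capable"])
        assert not bool(cats.loc["grp", "singleton_capable"])

    def test_invariant_to_duplicate_rows_and_idempotent(self):
        cultures = self._table({"c1": ["a"], "c2": ["a", "b"]})
        doubled = pd.concat([cultures, cultures], ignore_index=True)
        pd.testing.assert_frame_equal(ecology.classify_growth(cultures),
                                      ecology.classify_growth(doubled))


class TestAccumulationCurve:
    CULTURES = pd.DataFrame({
        "culture_id": ["c1", "c2", "c2", "c3"],
        "species_id": ["x", "x", "y", "z"]})

    def exact_mean(self, member_sets, k):
        """Average distinct species after k cultures over all orderings."""
        n = len(member_sets)
        totals = []
        for perm in itertools.permutations(range(n)):
            seen = set()
            for idx in perm[:k]:
                seen |= member_sets[idx]
            totals.append(len(seen))
        return sum(totals) / math.factorial(n)

    def test_enumeration_matches_hand_oracle(self):
        # cultures {x}, {x,y}, {z}: expected count after 2 cultures = 7/3
        sets = [frozenset({"x"}), frozenset({"x", "y"}), frozenset({"z"})]
        assert self.exact_mean(sets, 2) == pytest.approx(7 / 3)
        curve = ecology.accumulation_curve(self.CULTURES, method="enumerate")
        assert curve.mean[1] == pytest.approx(7 / 3)
        assert curve.mean[0] == pytest.approx(self.exact_mean(sets, 1))

    def test_shuffle_converges_to_enumeration(self):
        curve = ecology.accumulation_curve(self.CULTURES, n_permutations=20000,
                                           seed=0)
        assert curve.mean[1] == pytest.approx(7 / 3, abs=0.02)

    def test_final_k_is_total_richness_with_zero_sd(self):
        curve = ecology.accumulation_curve(self.CULTURES, n_permutations=50,
                                           seed=1)
        assert curve.mean[-1] == 3.0
        assert curve.sd[-1] == 0.0

    def test_identical_cultures_give_flat_curve(self):
        cultures = pd.DataFrame({
            "culture_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
            "species_id": ["a", "b"] * 3})
        curve = ecology.accumulation_curve(cultures, n_permutations=10, seed=2)
        assert np.allclose(curve.mean, 2.0)
        assert np.allclose(curve.sd, 0.0)

    def test_mean_curve_non_decreasing_and_k1_is_mean_richness(self):
        rng = np.random.default_rng(3)
        rows = [(f"c{i}", f"sp{rng.integers(0, 8)}")
                for i in range(7) for _ in range(rng.integers(1, 5))]
        cultures = pd.DataFrame(rows, columns=["culture_id", "species_id"])
        sizes = cultures.drop_duplicates().groupby("culture_id")[
            "species_id"].nunique()
        curve = ecology.accumulation_curve(cultures, n_permutations=4000,
                                           seed=4)
        assert (np.diff(curve.mean) >= 0).all()
        assert curve.mean[0] == pytest.approx(sizes.mean(), abs=0.1)

    def test_complexity_filter_restricts_cultures(self):
        cultures = pd.DataFrame({
            "culture_id": ["c1", "c2", "c2", "c3", "c3", "c3", "c3"],
            "species_id": ["x", "x", "y", "a", "b", "c", "d"]})
        curve = ecology.accumulation_curve(cultures, complexity_filter="gt3",
                                           n_permutations=5, seed=0)
        assert len(curve.k) == 1
        assert curve.mean[0] == 4.0

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="no cultures"):
            ecology.accumulation_curve(self.CULTURES, complexity_filter="gt3")

    def test_seeded_reproducibility(self):
        c1 = ecology.accumulation_curve(self.CULTURES, n_permutations=30, seed=9)
        c2 = ecology.accumulation_curve(self.CULTURES, n_permutations=30, seed=9)
        assert np.array_equal(c1.mean, c2.mean)
        assert np.array_equal(c1.sd, c2.sd)

    def test_bootstrap_method_reaches_lower_mean(self):
        # resampling with replacement can repeat cultures, so the curve
        # climbs no faster than the shuffle curve in expectation
        shuffle = ecology.accumulation_curve(self.CULTURES,
                                             n_permutations=4000, seed=5)
        boot = ecology.accumulation_curve(self.CULTURES, n_permutations=4000,
                                          seed=5, method="bootstrap")
        assert boot.method == "bootstrap"
        assert boot.mean[1] <= shuffle.mean[1] + 0.05
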