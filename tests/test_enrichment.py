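"""Group statistics, resampling nulls, and the confound controls."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from codonshift.enrichment import (
    GroupStats,
    abundance_matched_null,
    bin_by_frequency,
    exclusion_analysis,
    freq_change_correlation,
    group_stats,
    mrna_filter,
    resample_null,
)

from conftest import make_calls


class TestGroupStats:
    @pytest.mark.parametrize(
        "n,down,up,pct,du",
        [
            (148, 54, 10, 36.5, 5.4),
            (196, 45, 10, 23.0, 4.5),
            (2408, 231, 95, 9.6, 2.4),
            (1251, 226, 0, 18.1, None),
        ],
    )
    def test_worked_arithmetic_at_print_precision(self, n, down, up, pct, du):
        gs = GroupStats(n=n, n_down=down, n_up=up)
        assert round(gs.percent_down, 1) == pct
        if du is None:
            assert not gs.du_defined and math.isnan(gs.du)
        else:
            assert round(gs.du, 1) == du

    def test_all_quiet_group(self):
        gs = GroupStats(n=10, n_down=0, n_up=0)
        assert gs.percent_down == 0.0 and not gs.du_defined

    def test_counts_from_call_table(self):
        calls = make_calls(3, 2, 10)
        gs = group_stats(set(calls["gene_id"]), calls)
        assert (gs.n, gs.n_down, gs.n_up) == (10, 3, 2)

    def test_missing_member_raises(self):
        calls = make_calls(1, 1, 4)
        with pytest.raises(KeyError):
            group_stats({"absent"}, calls)


def enumerate_empirical_p(group_idx, pool_calls, statistic, observed):
    """Exhaustive empirical p over all equal-size subsets of the pool."""
    g = len(group_idx)
    hits = total = 0
    for subset in combinations(range(len(pool_calls)), g):
        sub = [pool_calls[i] for i in subset]
        nd, nu = sub.count("down"), sub.count("up")
        if statistic == "percent_down":
            hit = 100.0 * nd / g >= observed
        else:
            hit = nu == 0 or nd / nu >= observed
        hits += hit
        total += 1
    return hits / total


class TestResampleNull:
    def test_all_down_pool_always_ties(self):
        calls = pd.concat(
            [make_calls(5, 0, 5, prefix="g"), make_calls(20, 0, 20, prefix="p")],
            ignore_index=True,
        )
        group = {f"g{i:05d}" for i in range(5)}
        pool = {f"p{i:05d}" for i in range(20)}
        res = resample_null(group, pool, calls, "percent_down", n_samplings=500, seed=0)
        assert res.observed.percent_down == 100.0
        assert res.empirical_p == 1.0

    def test_no_down_pool_never_reaches(self):
        calls = pd.concat(
            [make_calls(3, 0, 5, prefix="g"), make_calls(0, 5, 20, prefix="p")],
            ignore_index=True,
        )
        group = {f"g{i:05d}" for i in range(5)}
        pool = {f"p{i:05d}" for i in range(20)}
        res = resample_null(group, pool, calls, "percent_down", n_samplings=500, seed=0)
        assert res.empirical_p == 0.0

    def test_pool_smaller_than_group_rejected(self):
        calls = make_calls(2, 1, 8)
        ids = list(calls["gene_id"])
        with pytest.raises(ValueError):
            resample_null(set(ids[:5]), set(ids[5:]), calls, "du")

    @pytest.mark.parametrize("statistic", ["percent_down", "du"])
    def test_matches_exhaustive_subset_enumeration(self, statistic):
        # 5-member group drawn from a 10-member pool: all C(10,5) subsets
        calls = pd.concat(
            [make_calls(3, 1, 5, prefix="g"), make_calls(4, 2, 10, prefix="p")],
            ignore_index=True,
        )
        group = {f"g{i:05d}" for i in range(5)}
        pool = [f"p{i:05d}" for i in range(10)]
        pool_calls = list(calls.set_index("gene_id").loc[pool, "call"])
        observed = group_stats(group, calls).statistic(statistic)
        exact = enumerate_empirical_p(range(5), pool_calls, statistic, observed)
        n = 40_000
        res = resample_null(group, set(pool), calls, statistic, n_samplings=n, seed=3)
        se = math.sqrt(exact * (1 - exact) / n)
        assert res.empirical_p == pytest.approx(exact, abs=max(3 * se, 1e-3))

    def test_convergence_across_sampling_depths(self):
        calls = pd.concat(
            [make_calls(6, 2, 20, prefix="g"), make_calls(30, 25, 300, prefix="p")],
            ignore_index=True,
        )
        group = {f"g{i:05d}" for i in range(20)}
        pool = {f"p{i:05d}" for i in range(300)}
        small = resample_null(group, pool, calls, "percent_down", n_samplings=2000, seed=1)
        big = resample_null(group, pool, calls, "percent_down", n_samplings=20000, seed=2)
        p = big.empirical_p
        se = math.sqrt(max(p * (1 - p), 1e-6) / 2000)
        assert small.empirical_p == pytest.approx(p, abs=3 * se)

    def test_reproducible_given_seed(self):
        calls = make_calls(10, 5, 50)
        ids = list(calls["gene_id"])
        a = resample_null(set(ids[:10]), set(ids[10:]), calls, "du", 3000, seed=7)
        b = resample_null(set(ids[:10]), set(ids[10:]), calls, "du", 3000, seed=7)
        assert a.empirical_p == b.empirical_p
        assert np.array_equal(a.null_values, b.null_values, equal_nan=True)


class TestAbundanceMatched:
    def test_flat_abundance_degenerates_to_plain_resampling(self):
        rng = np.random.default_rng(0)
        calls = make_calls(40, 20, 400)
        ids = list(calls["gene_id"])
        group = set(rng.choice(ids, 40, replace=False))
        pool = set(ids) - group
        abundance = pd.Series(1.0, index=ids)
        plain = resample_null(group, pool, calls, "percent_down", 20000, seed=5)
        matched = abundance_matched_null(group, pool, abundance, calls, "percent_down",
                                         n_bins=10, n_samplings=20000, seed=6)
        se = math.sqrt(max(plain.empirical_p * (1 - plain.empirical_p), 1e-6) / 20000)
        assert matched.empirical_p == pytest.approx(plain.empirical_p, abs=max(5 * se, 0.01))

    def test_unmatchable_bin_is_an_error(self):
        calls = make_calls(2, 1, 20)
        ids = list(calls["gene_id"])
        # group owns the entire top of the abundance range
        abundance = pd.Series(np.arange(20, dtype=float), index=ids)
        group = set(ids[-2:])
        pool = set(ids[:18])
        with pytest.raises(ValueError, match="bin"):
            abundance_matched_null(group, pool, abundance, calls, "percent_down",
                                   n_bins=10, n_samplings=100, seed=0)


class TestExclusion:
    def test_disjoint_groups_unchanged(self):
        calls = make_calls(4, 2, 12)
        ids = list(calls["gene_id"])
        groups = {"AGA": set(ids[:4]), "GAA": set(ids[4:8])}
        focal, other = exclusion_analysis("AGA", "GAA", groups, calls)
        assert (focal.n, other.n) == (4, 4)
        assert focal == group_stats(groups["AGA"], calls)

    def test_fully_overlapping_focal_flagged_empty(self):
        calls = make_calls(4, 2, 12)
        ids = list(calls["gene_id"])
        groups = {"AGA": set(ids[:4]), "GAA": set(ids[:6])}
        focal, other = exclusion_analysis("AGA", "GAA", groups, calls)
        assert focal is None
        assert other.n == 2

    def test_hand_recount_of_co_enriched(self):
        # 6-gene focal group, 2 of them co-enriched: recount by hand
        calls = make_calls(3, 1, 10)  # p00000..p00002 down, p00003 up
        ids = list(calls["gene_id"])
        groups = {"AGA": set(ids[:6]), "GAA": {ids[0], ids[3], ids[8], ids[9]}}
        focal, _ = exclusion_analysis("AGA", "GAA", groups, calls)
        # remaining: ids 1,2 (down), 4,5 (unchanged)
        assert (focal.n, focal.n_down, focal.n_up) == (4, 2, 0)


class TestMrnaFilter:
    @staticmethod
    def mrna(gene, log2fc, p):
        return pd.DataFrame({"gene_id": [gene], "log2fc": [log2fc], "p": [p]})

    def test_unchanged_mrna_retains_protein(self):
        calls = make_calls(1, 0, 1)
        kept, removed = mrna_filter(calls, self.mrna("p00000", 0.0, 0.9))
        assert removed == 0 and len(kept) == 1

    def test_same_direction_mrna_removes_protein(self):
        calls = make_calls(1, 0, 1)
        kept, removed = mrna_filter(calls, self.mrna("p00000", -1.0, 0.001))
        assert removed == 1 and len(kept) == 0

    def test_opposite_direction_retained(self):
        calls = make_calls(1, 0, 1)
        kept, removed = mrna_filter(calls, self.mrna("p00000", 1.0, 0.001))
        assert removed == 0

    def test_absent_gene_passes_through(self):
        calls = make_calls(1, 0, 1)
        kept, removed = mrna_filter(calls, self.mrna("other", -1.0, 0.001))
        assert removed == 0 and len(kept) == 1


class TestFrequencyBins:
    @staticmethod
    def usage(freqs):
        return pd.DataFrame(
            {
                "gene_id": [f"p{i:05d}" for i in range(len(freqs))],
                "codon": "AGA",
                "freq_per_1000": freqs,
            }
        )

    def test_left_closed_boundary(self):
        calls = make_calls(1, 0, 1)
        bins = bin_by_frequency(calls, self.usage([10.0]), "AGA")
        assert bins.loc[1, "n"] == 1 and bins.loc[0, "n"] == 0

    def test_single_populated_bin(self):
        calls = make_calls(2, 1, 5)
        bins = bin_by_frequency(calls, self.usage([1, 3, 5, 7, 9]), "AGA")
        assert bins.loc[0, "n"] == 5
        assert bins.loc[0, "du"] == 2.0
        assert bins["n"].sum() == 5

    def test_last_bin_open_ended(self):
        calls = make_calls(1, 0, 1)
        bins = bin_by_frequency(calls, self.usage([250.0]), "AGA")
        assert bins.loc[6, "n"] == 1


class TestCorrelation:
    def test_perfect_monotone_decreasing(self):
        rho, _ = freq_change_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_small_example_rank_formula(self):
        rho, _ = freq_change_correlation([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            freq_change_correlation([1, 1, 1], [1, 2, 3])

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        rho, _ = freq_change_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho) < 0.1
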