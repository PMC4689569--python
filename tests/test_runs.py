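"""Window profiles, k-mer run counting, and composition-preserving shuffle nulls."""

from collections import Counter
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonshift.codon_stats import SENSE_CODONS, CodingSequence
from codonshift.runs import (
    compare_run_vectors,
    count_runs,
    run_null,
    run_null_table,
    shuffle_codons,
    window_profile,
)

TARGETS = frozenset({"AGA", "GAA"})
codon_lists = st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=50)


def exact_mw_p_two_sided(a, b):
    """Two-sided Mann-Whitney p by enumeration of all group assignments."""
    from itertools import combinations as combs

    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    us = []
    for idx in combs(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    dev = abs(obs - mean_u)
    return sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12) / len(us)


def null_run_mean_exhaustive(n, m, k):
    """Mean k-run count over all distinct placements of m targets in n slots."""
    counts = []
    for pos in combinations(range(n), m):
        ind = np.zeros(n, dtype=bool)
        ind[list(pos)] = True
        counts.append(sum(ind[i : i + k].all() for i in range(n - k + 1)))
    return float(np.mean(counts))


class TestWindowProfile:
    def test_all_target_gene_centers_to_zero(self):
        prof = window_profile(CodingSequence("g", ("AGA",) * 20), TARGETS, w=15)
        assert np.allclose(prof.values, 0.0)

    def test_no_targets_is_flat_zero(self):
        prof = window_profile(CodingSequence("g", ("ATG",) * 20), TARGETS, w=15)
        assert np.allclose(prof.values, 0.0)

    def test_window_count_formula(self):
        prof = window_profile(CodingSequence("g", ("ATG",) * 16), TARGETS, w=15)
        assert prof.values.size == 2

    def test_short_gene_empty_profile(self):
        prof = window_profile(CodingSequence("g", ("ATG",) * 5), TARGETS, w=15)
        assert prof.values.size == 0

    def test_localized_cluster_peaks_positive(self):
        codons = ("ATG",) * 30 + ("AGA",) * 5 + ("ATG",) * 30
        prof = window_profile(CodingSequence("g", codons), TARGETS, w=15)
        assert prof.values.max() > 0 > prof.values.min()


class TestCountRuns:
    @pytest.mark.parametrize(
        "codons,k,expect",
        [
            (("AGA", "AGA", "AGA", "AGA"), 3, 2),
            (("AGA", "GAA", "AGA"), 3, 1),
            (("AGA", "ATG", "AGA", "GAA"), 3, 0),
        ],
        ids=["overlapping", "mixed-combination", "interrupted"],
    )
    def test_examples(self, codons, k, expect):
        assert count_runs(CodingSequence("g", codons), TARGETS, k=k) == expect

    @settings(deadline=None, derandomize=True)
    @given(codon_lists)
    def test_monotone_nonincreasing_in_k(self, codons):
        cds = CodingSequence("g", tuple(codons))
        counts = [count_runs(cds, TARGETS, k=k) for k in (2, 3, 4, 5)]
        assert counts == sorted(counts, reverse=True)


class TestShuffle:
    @settings(deadline=None, derandomize=True)
    @given(codon_lists, st.integers(0, 2**31 - 1))
    def test_multiset_preserved(self, codons, seed):
        cds = CodingSequence("g", tuple(codons))
        shuffled = shuffle_codons(cds, np.random.default_rng(seed))
        assert Counter(shuffled.codons) == Counter(cds.codons)

    def test_fixed_seed_reproducible(self):
        cds = CodingSequence("g", tuple(np.random.default_rng(3).choice(SENSE_CODONS, 40)))
        a = shuffle_codons(cds, np.random.default_rng(42))
        b = shuffle_codons(cds, np.random.default_rng(42))
        assert a.codons == b.codons

    def test_singleton_unchanged(self):
        cds = CodingSequence("g", ("AGA",))
        assert shuffle_codons(cds, np.random.default_rng(0)).codons == ("AGA",)


class TestRunNull:
    def test_saturated_gene_ties_every_shuffle(self):
        rec = run_null(CodingSequence("g", ("AGA",) * 10), TARGETS, k=3, n_shuffles=50, seed=0)
        assert rec.empirical_p == 1.0
        assert np.all(rec.null_counts == rec.actual)

    def test_too_few_targets(self):
        rec = run_null(CodingSequence("g", ("AGA", "ATG", "ATG")), TARGETS, k=3,
                       n_shuffles=20, seed=0)
        assert rec.actual == 0 and rec.null_mean == 0.0 and rec.empirical_p == 1.0

    def test_null_mean_matches_exhaustive_enumeration(self):
        # 6 codons, 3 targets, k=3: exact mean over C(6,3) placements
        cds = CodingSequence("g", ("AGA", "GAA", "AGA", "ATG", "TTT", "GGT"))
        expected = null_run_mean_exhaustive(6, 3, 3)
        rec = run_null(cds, TARGETS, k=3, n_shuffles=20_000, seed=1)
        mc_se = rec.null_counts.std(ddof=1) / np.sqrt(rec.null_counts.size)
        assert rec.null_mean == pytest.approx(expected, abs=max(3 * mc_se, 0.01))

    def test_random_genes_are_calibrated(self):
        # no planted clustering: empirical p centers near 0.5, actual ~ null mean
        rng = np.random.default_rng(9)
        genes = []
        for i in range(200):
            codons = np.array(["ATG"] * 80, dtype=object)
            codons[rng.choice(80, size=12, replace=False)] = rng.choice(["AGA", "GAA"], 12)
            genes.append(CodingSequence(f"g{i}", tuple(codons)))
        tab = run_null_table(genes, TARGETS, k=3, n_shuffles=400, master_seed=9)
        assert 0.3 < tab["empirical_p"].median() <= 1.0
        diff = tab["actual"] - tab["null_mean"]
        assert abs(diff.mean()) < 3 * diff.std(ddof=1) / np.sqrt(len(diff))

    def test_planted_runs_exceed_null(self):
        # a planted run of length k+2 should beat the shuffle null nearly always
        rng = np.random.default_rng(4)
        genes = []
        for i in range(40):
            codons = np.array(["ATG"] * 120, dtype=object)
            start = int(rng.integers(1, 110))
            codons[start : start + 5] = rng.choice(["AGA", "GAA"], 5)
            genes.append(CodingSequence(f"g{i}", tuple(codons)))
        tab = run_null_table(genes, TARGETS, k=3, n_shuffles=300, master_seed=4)
        assert (tab["actual"] > tab["null_mean"]).mean() >= 0.95


class TestCompareRunVectors:
    def test_identical_vectors(self):
        u, p = compare_run_vectors([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_jointly_constant(self):
        u, p = compare_run_vectors([2, 2, 2], [2, 2])
        assert (u, p) == (3.0, 1.0)

    def test_separated_groups_significant(self):
        a, b = [5, 6, 7, 8], [1, 2, 3, 4]
        u, p = compare_run_vectors(a, b)
        assert p == pytest.approx(exact_mw_p_two_sided(a, b), rel=1e-9)
        assert p < 0.05

    def test_singleton_exact(self):
        u, p = compare_run_vectors([1.0], [2.0])
        assert p == pytest.approx(exact_mw_p_two_sided([1.0], [2.0]), rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_run_vectors([], [1.0])
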