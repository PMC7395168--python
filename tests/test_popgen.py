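"""Diversity/differentiation statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import A, H, M, R, make_matrix
from pumpkinpop import popgen
from pumpkinpop.datamodel import PopulationMap, ValidationError


# ---------------------------------------------------------------------------
# oracles: scalar transcriptions / enumerations, independent of the package's
# vectorized implementations


def wc_components_oracle(pop_genotypes):
    """Weir-Cockerham (1984) a/b/c for one locus, two populations.

    ``pop_genotypes`` is a list of two lists of (allele1, allele2) tuples
    with alleles coded 0/1. Direct scalar transcription of the published
    component formulas.
    """
    r = 2
    n = [len(g) for g in pop_genotypes]
    p = [sum(a + b for a, b in g) / (2 * len(g)) for g in pop_genotypes]
    h = [sum(1 for a, b in g if a != b) / len(g) for g in pop_genotypes]
    n_tot = sum(n)
    nbar = n_tot / r
    nc = (n_tot - sum(ni**2 for ni in n) / n_tot) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / n_tot
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / n_tot
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def richness_oracle(copy_counts, g):
    """Mean number of distinct alleles over every g-subset of the gene copies."""
    copies = [allele for allele, n in enumerate(copy_counts) for _ in range(int(n))]
    subsets = list(itertools.combinations(range(len(copies)), g))
    total = sum(len({copies[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


def nei_D_oracle(freqs_a, freqs_b, n_a, n_b):
    """Nei (1978) unbiased D from per-locus alt frequencies and diploid counts."""
    jxy = [pa * pb + (1 - pa) * (1 - pb) for pa, pb in zip(freqs_a, freqs_b)]
    jx = [
        (2 * n_a * (p**2 + (1 - p) ** 2) - 1) / (2 * n_a - 1) for p in freqs_a
    ]
    jy = [
        (2 * n_b * (p**2 + (1 - p) ** 2) - 1) / (2 * n_b - 1) for p in freqs_b
    ]
    identity = (sum(jxy) / len(jxy)) / math.sqrt(
        (sum(jx) / len(jx)) * (sum(jy) / len(jy))
    )
    return -math.log(identity)


def calls_to_allele_pairs(column):
    pairs = {R: (0, 0), H: (0, 1), A: (1, 1)}
    return [pairs[c] for c in column if c != M]


# ---------------------------------------------------------------------------


class TestAlleleFrequencies:
    def test_symmetric_trio(self):
        spec = popgen.allele_frequencies(make_matrix([[R], [H], [A]]))
        assert spec.p_alt[0] == pytest.approx(0.5)
        assert spec.gene_copies[0] == 6

    def test_fixed_reference(self):
        spec = popgen.allele_frequencies(make_matrix([[R], [R]]))
        assert spec.p_alt[0] == 0.0

    def test_missing_excluded_from_copies(self):
        spec = popgen.allele_frequencies(make_matrix([[H], [M], [A]]))
        assert spec.gene_copies[0] == 4
        assert spec.p_alt[0] == pytest.approx(3 / 4)

    def test_zero_copy_marker_flagged(self):
        spec = popgen.allele_frequencies(make_matrix([[M], [M]]))
        assert np.isnan(spec.p_alt[0]) and not spec.defined[0]


class TestPic:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((1.0, 0.0), 0.0),
            ((0.5, 0.5), 0.375),
            ((0.9, 0.1), 0.1638),
        ],
    )
    def test_printed_formula_values(self, freqs, expected):
        assert popgen.pic(np.array(freqs)) == pytest.approx(expected, abs=1e-12)
        assert popgen.pic_biallelic(np.array([freqs[1]]))[0] == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.0, 1.0))
    def test_pic_below_uncorrected_he(self, p):
        """PIC <= 1 - sum(p^2) <= 0.5 for bi-allelic markers."""
        he_raw = 1 - p**2 - (1 - p) ** 2
        pic = popgen.pic(np.array([p, 1 - p]))
        assert pic <= he_raw + 1e-12
        assert he_raw <= 0.5 + 1e-12

    def test_general_formula_matches_biallelic_shortcut(self):
        rng = np.random.default_rng(4)
        for p in rng.uniform(0, 1, size=10):
            assert popgen.pic(np.array([1 - p, p])) == pytest.approx(
                float(popgen.pic_biallelic(np.array([p]))[0]), abs=1e-12
            )


class TestExpectedHet:
    def test_monomorphic_is_zero(self):
        assert popgen.expected_het_unbiased(np.array([0.0]), np.array([10]))[0] == 0.0

    def test_small_sample_correction(self):
        he = popgen.expected_het_unbiased(np.array([0.5]), np.array([10]))[0]
        assert he == pytest.approx(20 / 19 * 0.5, abs=1e-12)

    def test_large_n_limit(self):
        he = popgen.expected_het_unbiased(np.array([0.5]), np.array([10**7]))[0]
        assert he == pytest.approx(0.5, abs=1e-6)

    def test_undefined_below_two_diploids(self):
        assert np.isnan(popgen.expected_het_unbiased(np.array([0.5]), np.array([1]))[0])


class TestAllelicRichness:
    def test_single_allele_is_one(self):
        for g in (1, 4, 8):
            assert popgen.allelic_richness(np.array([8, 0]), g) == pytest.approx(1.0)

    def test_full_sample_counts_observed_alleles(self):
        assert popgen.allelic_richness(np.array([6, 2]), 8) == pytest.approx(2.0)

    def test_hypergeometric_value(self):
        # (1 - 0) + (1 - C(6,4)/C(8,4)) = 2 - 15/70
        assert popgen.allelic_richness(np.array([6, 2]), 4) == pytest.approx(
            2 - 15 / 70, abs=1e-12
        )

    @pytest.mark.parametrize("counts,g", [((6, 2), 4), ((5, 3), 2), ((7, 1), 5), ((4, 4), 3)])
    def test_matches_enumeration_oracle(self, counts, g):
        expected = richness_oracle(counts, g)
        assert popgen.allelic_richness(np.array(counts), g) == pytest.approx(
            expected, abs=1e-10
        )

    def test_monotone_in_g(self):
        values = [popgen.allelic_richness(np.array([6, 2]), g) for g in range(1, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_g_above_copies_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            popgen.allelic_richness(np.array([3, 1]), 5)


class TestPairwiseFst:
    def test_fixed_difference_theta_one(self):
        matrix = make_matrix([[R], [R], [R], [A], [A], [A]])
        res = popgen.pairwise_fst(matrix, ["acc0", "acc1", "acc2"], ["acc3", "acc4", "acc5"])
        assert res.theta == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        matrix = make_matrix([[R, H], [H, A], [R, H], [H, A]])
        res = popgen.pairwise_fst(matrix, ["acc0", "acc1"], ["acc2", "acc3"])
        assert res.theta <= 0.0

    def test_single_locus_matches_oracle(self):
        # popA = {hom_ref, hom_ref, het}, popB = {hom_alt, hom_alt, het}
        matrix = make_matrix([[R], [R], [H], [A], [A], [H]])
        res = popgen.pairwise_fst(matrix, ["acc0", "acc1", "acc2"], ["acc3", "acc4", "acc5"])
        a, b, c = wc_components_oracle(
            [calls_to_allele_pairs([R, R, H]), calls_to_allele_pairs([A, A, H])]
        )
        assert res.a_sum == pytest.approx(a, abs=1e-10)
        assert res.b_sum == pytest.approx(b, abs=1e-10)
        assert res.c_sum == pytest.approx(c, abs=1e-10)
        assert res.theta == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_multilocus_unequal_sizes_matches_oracle(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(6, 5))
        matrix = make_matrix(calls)
        pa = ["acc0", "acc1"]
        pb = ["acc2", "acc3", "acc4", "acc5"]
        res = popgen.pairwise_fst(matrix, pa, pb)
        a_sum = b_sum = c_sum = 0.0
        for j in range(5):
            a, b, c = wc_components_oracle(
                [
                    calls_to_allele_pairs(calls[:2, j]),
                    calls_to_allele_pairs(calls[2:, j]),
                ]
            )
            a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
        assert res.theta == pytest.approx(a_sum / (a_sum + b_sum + c_sum), abs=1e-10)

    def test_theta_invariant_under_pop_swap_and_allele_relabel(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 3, size=(8, 10))
        matrix = make_matrix(calls)
        pa = [f"acc{i}" for i in range(4)]
        pb = [f"acc{i}" for i in range(4, 8)]
        t = popgen.pairwise_fst(matrix, pa, pb).theta
        assert popgen.pairwise_fst(matrix, pb, pa).theta == pytest.approx(t, abs=1e-12)
        flipped = make_matrix(2 - calls)
        assert popgen.pairwise_fst(flipped, pa, pb).theta == pytest.approx(t, abs=1e-12)

    def test_no_shared_locus_rejected(self):
        matrix = make_matrix([[R, M], [R, M], [M, A], [M, A]])
        with pytest.raises(ValidationError, match="shared"):
            popgen.pairwise_fst(matrix, ["acc0", "acc1"], ["acc2", "acc3"])


class TestNeiDistance:
    def test_identical_frequencies_large_n_near_zero(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(200, 50))
        calls = np.vstack([calls, calls])  # popB duplicates popA exactly
        matrix = make_matrix(calls)
        pa = [f"acc{i}" for i in range(200)]
        pb = [f"acc{i}" for i in range(200, 400)]
        assert abs(popgen.nei_distance(matrix, pa, pb)) < 0.01

    def test_fixed_differences_infinite(self):
        matrix = make_matrix([[R, R], [R, R], [A, A], [A, A]])
        assert popgen.nei_distance(matrix, ["acc0", "acc1"], ["acc2", "acc3"]) == float("inf")

    def test_three_locus_oracle(self):
        # popA genotypes chosen to give freqs (0.25, 0.5, 0.0), popB (0.75, 0.5, 0.25)
        pa_calls = [[R, R, R], [R, A, R], [H, H, R], [R, H, R]]
        pb_calls = [[A, H, R], [A, R, H], [H, A, R], [A, H, R]]
        matrix = make_matrix(pa_calls + pb_calls)
        pa = [f"acc{i}" for i in range(4)]
        pb = [f"acc{i}" for i in range(4, 8)]
        spec_a = popgen.allele_frequencies(matrix, pa)
        spec_b = popgen.allele_frequencies(matrix, pb)
        expected = nei_D_oracle(list(spec_a.p_alt), list(spec_b.p_alt), 4, 4)
        assert popgen.nei_distance(matrix, pa, pb) == pytest.approx(expected, abs=1e-10)


def _two_pop_map(n_a, n_b, names=("popA", "popB")):
    assignments = {}
    for i in range(n_a + n_b):
        pop = names[0] if i < n_a else names[1]
        assignments[f"acc{i}"] = (pop, "breeding_line")
    return PopulationMap(assignments, frozenset(names))


class TestPermutationTest:
    def test_fixed_difference_minimal_p(self):
        # with 15+15 the chance a random relabelling recreates the perfect
        # split is 2/C(30,15) ~ 1e-8, so no permuted theta reaches 1
        matrix = make_matrix([[R]] * 15 + [[A]] * 15)
        res = popgen.fst_permutation_test(matrix, _two_pop_map(15, 15), 999, seed=0)
        assert res[0].p_value == pytest.approx(1 / 1000)
        assert res[0].bonferroni_significant

    def test_identical_populations_not_significant(self):
        rng = np.random.default_rng(5)
        calls = np.tile(rng.integers(0, 3, size=(10, 30)), (2, 1))
        matrix = make_matrix(calls)
        res = popgen.fst_permutation_test(matrix, _two_pop_map(10, 10), 999, seed=42)
        assert res[0].p_value > 0.05

    def test_same_seed_reproduces_p_values(self):
        rng = np.random.default_rng(9)
        matrix = make_matrix(rng.integers(0, 3, size=(12, 20)))
        p1 = [r.p_value for r in popgen.fst_permutation_test(matrix, _two_pop_map(6, 6), 200, seed=7)]
        p2 = [r.p_value for r in popgen.fst_permutation_test(matrix, _two_pop_map(6, 6), 200, seed=7)]
        assert p1 == p2

    def test_bonferroni_over_tested_pairs(self):
        # three populations -> 3 pairs; flags use alpha/3
        rng = np.random.default_rng(13)
        assignments = {}
        for i in range(12):
            assignments[f"acc{i}"] = (f"pop{i % 3}", "landrace")
        popmap = PopulationMap(assignments, frozenset({"pop0", "pop1", "pop2"}))
        matrix = make_matrix(rng.integers(0, 3, size=(12, 15)))
        res = popgen.fst_permutation_test(matrix, popmap, 99, seed=0, alpha=0.05)
        assert len(res) == 3
        for r in res:
            assert r.bonferroni_significant == (r.p_value <= 0.05 / 3)


class TestDiversitySummary:
    def test_identical_inbreds_floor_values(self):
        calls = np.tile(np.array([[R, A, R, A]], dtype=np.int8), (5, 1))
        matrix = make_matrix(calls)
        assignments = {f"acc{i}": ("popA", "breeding_line") for i in range(5)}
        stats = popgen.diversity_summary(matrix, PopulationMap(assignments, {"popA"}))
        by_pop = {s.population: s for s in stats}
        assert by_pop["popA"].allelic_richness == pytest.approx(1.0)
        assert by_pop["popA"].he == pytest.approx(0.0)
        assert by_pop["popA"].pic == pytest.approx(0.0)

    def test_unknown_accessions_excluded(self):
        calls = np.array([[R], [A], [H], [H]], dtype=np.int8)
        matrix = make_matrix(calls)
        assignments = {
            "acc0": ("popA", "F1"),
            "acc1": ("popA", "F1"),
            "acc2": ("unknown", "unknown"),
            "acc3": ("popA", "F1"),
        }
        stats = popgen.diversity_summary(matrix, PopulationMap(assignments, {"popA"}))
        total = next(s for s in stats if s.population == "Total")
        assert total.sample_size == 3
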