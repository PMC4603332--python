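"""Contig-joining combinatorics, a-priori probability and the DP log base."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

import adjscaff as A
from adjscaff.prior import phase_change_threshold
from adjscaff.trees import InputError
from helpers import enumerate_scaffolding_solutions


class TestCountSolutions:
    @pytest.mark.parametrize("n,p,expected", [
        (1, 1, 1),      # base case of the closed form
        (1, 2, 0),      # more chromosomes than contigs
        (2, 1, 4),      # 2 orders x 2 relative orientations
        (3, 1, 24),
        (4, 4, 1),      # nothing to join
        (5, 0, 0),
    ])
    def test_known_values(self, n, p, expected):
        assert A.count_solutions(n, p) == expected
        assert A.count_solutions_by_recurrence(n, p) == expected

    def test_identity_when_fully_joined(self):
        for n in range(1, 12):
            assert A.count_solutions(n, n) == 1

    def test_closed_form_equals_recurrence_and_enumeration(self):
        # three independent routes agree for every 1 <= p <= n <= 6
        for n in range(1, 7):
            for p in range(1, n + 1):
                closed = A.count_solutions(n, p)
                assert closed == A.count_solutions_by_recurrence(n, p)
                assert closed == enumerate_scaffolding_solutions(n, p)

    def test_closed_form_equals_recurrence_large(self):
        for n in range(7, 31):
            for p in (1, 2, n // 2, n - 1, n):
                assert A.count_solutions(n, p) == \
                    A.count_solutions_by_recurrence(n, p)

    def test_rejects_zero_contigs(self):
        with pytest.raises(InputError):
            A.count_solutions(0, 1)

    @given(st.integers(min_value=2, max_value=80),
           st.data())
    def test_join_ratio_conservation(self, n, data):
        # summing f(n-1,p)/f(n,p) over the 2n(n-1) ordered extremity pairs
        # from distinct contigs yields the expected number of joins, n - p
        p = data.draw(st.integers(min_value=1, max_value=n))
        ratio = Fraction(A.count_solutions(n - 1, p), A.count_solutions(n, p)) \
            if A.count_solutions(n, p) else Fraction(0)
        assert 2 * n * (n - 1) * ratio == n - p

    def test_ratio_equals_fragmentation_measure(self):
        for n in range(2, 30):
            for p in range(1, n + 1):
                ratio = A.count_solutions(n - 1, p) / A.count_solutions(n, p)
                assert ratio == pytest.approx(A.fragmentation(n, p), abs=1e-12)


@pytest.fixture
def fragmented_assembly():
    # 3 contigs: path a-b-c, path d-e, singleton f; one chromosome expected
    adj = [("a", "b"), ("b", "c"), ("d", "e")]
    return A.build_assembly("X", "abcdef", adj, 1)


class TestRho:
    def test_values(self, fragmented_assembly):
        asm = fragmented_assembly
        single = A.build_assembly("Y", "pq", [], 2)
        assert A.rho("p", "q", single) == 4          # two singleton contigs
        assert A.rho("f", "a", asm) == 2             # singleton vs path end
        assert A.rho("a", "d", asm) == 1             # two path ends


class TestPriorProbability:
    def test_observed_is_one(self, fragmented_assembly):
        assert A.prior_probability("a", "b", fragmented_assembly) == 1.0

    def test_fully_assembled_is_zero(self):
        asm = A.build_assembly("X", "abcd",
                               [("a", "b"), ("b", "c"), ("c", "d")], 1)
        assert A.prior_probability("a", "d", asm) == 0.0

    def test_free_end_pair_matches_count_ratio(self, fragmented_assembly):
        # rho=1 pair: (n-p)/(2n(n-1)) = 2/12 = 1/6 = f(2,1)/f(3,1)
        p = A.prior_probability("a", "d", fragmented_assembly)
        assert p == pytest.approx(1 / 6)
        assert p == pytest.approx(A.count_solutions(2, 1) / A.count_solutions(3, 1))

    def test_singleton_pair_scales_by_rho(self):
        # n=3, p=1, two singleton contigs: 4 * 2/12 = 2/3
        asm = A.build_assembly("X", "abcde",
                               [("a", "b"), ("b", "c")], 1)
        assert A.prior_probability("d", "e", asm) == pytest.approx(2 / 3)

    def test_internal_gene_gets_zero(self, fragmented_assembly):
        assert A.prior_probability("b", "f", fragmented_assembly) == 0.0

    def test_same_contig_gets_zero(self, fragmented_assembly):
        assert A.prior_probability("a", "c", fragmented_assembly) == 0.0

    def test_different_species_gene_rejected(self, fragmented_assembly):
        with pytest.raises(InputError):
            A.prior_probability("a", "a", fragmented_assembly)

    def test_gene_level_conservation(self):
        # sum of rho-weighted priors over eligible unordered gene pairs
        # equals the expected number of joins n - p
        for seed, orders in enumerate((
                [["a", "b", "c"], ["d", "e"], ["f"]],
                [["a"], ["b"], ["c"], ["d"]],
                [["a", "b"], ["c", "d"], ["e", "f", "g"], ["h"]],
        )):
            genes = [g for o in orders for g in o]
            adj = A.adjacencies_from_gene_order(orders)
            asm = A.build_assembly("X", genes, adj, 1)
            total = sum(
                A.prior_probability(g1, g2, asm)
                for i, g1 in enumerate(genes) for g2 in genes[i + 1:]
                if not asm.is_observed(g1, g2)
            )
            assert total == pytest.approx(asm.n - asm.p, abs=1e-9)

    def test_expected_joins_grow_with_fragmentation(self):
        # per-pair P shrinks as more contigs compete for each extremity
        # (for p=1 it is rho/(2n)), but the total expected number of
        # joins n - p grows with fragmentation
        pair_p, totals = [], []
        for extra in range(3, 10):
            orders = [["a1", "a2"], ["b1", "b2"]] + \
                [[f"c{i}x", f"c{i}y"] for i in range(extra)]
            genes = [g for o in orders for g in o]
            asm = A.build_assembly("X", genes,
                                   A.adjacencies_from_gene_order(orders), 1)
            pair_p.append(A.prior_probability("a1", "b1", asm))
            totals.append(asm.n - asm.p)
        assert pair_p == sorted(pair_p, reverse=True)
        assert totals == sorted(totals)
        assert pair_p[0] == pytest.approx(1 / (2 * 5))  # n=5 contigs, rho=1


class TestLogBase:
    def test_threshold_example(self):
        # p(S) = 1/6 (n=3, p=1), Br=1: threshold 5, base 5.25
        assert phase_change_threshold(1 / 6, 1.0) == pytest.approx(5.0)
        assert A.log_base(3, 1, 1.0) == pytest.approx(5.25)

    def test_threshold_at_half(self):
        assert phase_change_threshold(0.5, 1.0) == pytest.approx(1.0)

    def test_perfect_assembly_has_no_base(self):
        with pytest.raises(InputError):
            A.log_base(3, 3, 1.0)
        assert phase_change_threshold(0.0, 1.0) == math.inf

    @given(st.integers(min_value=2, max_value=200), st.data())
    def test_systematic_proposal_guarantee(self, n, data):
        # with b just above the threshold, c1 < c0 + Br for any rho=1
        # eligible pair: an adjacency inferred in the parent is proposed
        p = data.draw(st.integers(min_value=1, max_value=n - 1))
        br = data.draw(st.sampled_from([0.5, 1.0, 2.0]))
        b = A.log_base(n, p, br)
        prob = A.fragmentation(n, p)
        c1 = -math.log(prob) / math.log(b)
        c0 = -math.log(1 - prob) / math.log(b)
        assert c1 < c0 + br


class TestFragmentationProfile:
    def test_from_assembly(self, fragmented_assembly):
        prof = A.FragmentationProfile.from_assembly(fragmented_assembly, 1.0)
        assert prof.n == 3 and prof.p == 1
        assert prof.p_s == pytest.approx(1 / 6)
        assert prof.base == pytest.approx(5.25)

    def test_fully_assembled_profile(self):
        asm = A.build_assembly("X", "ab", [("a", "b")], 1)
        prof = A.FragmentationProfile.from_assembly(asm, 1.0)
        assert prof.p_s == 0.0
        assert prof.base is None
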