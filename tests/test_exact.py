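"""Unit and property tests of the exact intersection probability model."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from exactsets import (
    SizedSets,
    expected_overlap,
    fold_enrichment,
    log_binomial,
    overlap_pmf,
    overlap_pmf_exhaustive,
    overlap_pmf_naive,
    overlap_pmf_two,
    overlap_tail,
)
from exactsets.exact import counters


class TestLogBinomial:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (10, 0, 0.0),
            (10, 10, 0.0),
            (10, 11, float("-inf")),
            (10, -1, float("-inf")),
            (10, 4, math.log(210)),  # C(10,4) = 210 by integer arithmetic
        ],
    )
    def test_examples(self, n, k, expected):
        assert log_binomial(n, k) == pytest.approx(expected, rel=1e-12)

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            log_binomial(-1, 0)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 300), st.integers(0, 300))
    def test_matches_exact_integer_arithmetic(self, n, k):
        if k > n:
            assert log_binomial(n, k) == float("-inf")
        else:
            assert log_binomial(n, k) == pytest.approx(math.log(math.comb(n, k)), rel=1e-12)


class TestTwoSetDensity:
    def test_exact_rational_value(self):
        # C(5,2) C(5,2) / C(10,4) = 100/210 by exact rational arithmetic
        assert overlap_pmf_two(2, 5, 4, 10) == pytest.approx(float(Fraction(100, 210)), rel=1e-12)

    def test_empty_set_shares_nothing(self):
        assert overlap_pmf_two(0, 5, 0, 10) == 1.0

    def test_outside_support_is_zero(self):
        assert overlap_pmf_two(5, 5, 4, 10) == 0.0
        assert overlap_pmf_two(0, 8, 7, 10) == 0.0  # below max(0, a+b-n)

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_pmf_two(2, 11, 4, 10)

    def test_matches_scipy_hypergeometric(self):
        for a, b, n in [(5, 4, 10), (30, 50, 120), (7, 7, 7)]:
            for x in range(min(a, b) + 1):
                assert overlap_pmf_two(x, a, b, n) == pytest.approx(
                    hypergeom.pmf(x, n, a, b), rel=1e-10, abs=1e-300
                )


class TestForwardAlgorithm:
    def test_two_sets_reduce_to_hypergeometric(self):
        sets = SizedSets((5, 4), 10)
        for x in range(5):
            expected = hypergeom.pmf(x, 10, 5, 4)
            got = math.exp(overlap_pmf(sets, x))
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize(
        "sizes,n",
        [
            ((3, 4, 5), 8),
            ((10, 15, 20, 25), 60),
            ((6, 6, 6, 6, 6), 20),
            ((2, 9, 9), 10),
        ],
    )
    def test_matches_naive_nested_sum(self, sizes, n):
        sets = SizedSets(sizes, n)
        for x in range(min(sizes) + 1):
            naive = overlap_pmf_naive(sets, x)
            forward = overlap_pmf(sets, x)
            if naive == float("-inf"):
                assert forward < -600 or forward == float("-inf")
            else:
                assert forward == pytest.approx(naive, rel=1e-10)

    def test_matches_exhaustive_enumeration(self):
        sets = SizedSets((3, 4, 5), 8)
        for x in range(4):
            exact = overlap_pmf_exhaustive(sets, x)
            if exact == 0:
                assert overlap_pmf(sets, x) < -20
            else:
                assert math.exp(overlap_pmf(sets, x)) == pytest.approx(float(exact), rel=1e-10)

    def test_above_max_overlap_is_zero(self):
        assert overlap_pmf(SizedSets((3, 4, 5), 8), 4) == float("-inf")

    def test_negative_overlap_rejected(self):
        with pytest.raises(ValueError):
            overlap_pmf(SizedSets((3, 4), 8), -1)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.integers(5, 50).flatmap(
            lambda n: st.tuples(
                st.just(n), st.lists(st.integers(1, n), min_size=2, max_size=5)
            )
        )
    )
    def test_normalization(self, n_and_sizes):
        n, sizes = n_and_sizes
        sets = SizedSets(tuple(sizes), n)
        total = sum(math.exp(overlap_pmf(sets, x)) for x in range(min(sizes) + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.permutations([4, 9, 13, 6]),
        st.integers(0, 4),
    )
    def test_permutation_invariance(self, sizes, x):
        n = 30
        reference = overlap_pmf(SizedSets((4, 9, 13, 6), n), x)
        permuted = overlap_pmf(SizedSets(tuple(sizes), n), x)
        if reference == float("-inf"):
            assert permuted == float("-inf")
        else:
            assert permuted == pytest.approx(reference, rel=1e-12)

    def test_operation_count_linear_in_set_number(self):
        """Forward cost is O(t * m^2): doubling t roughly doubles the work."""
        n, m = 400, 40

        def ops(t):
            sizes = tuple([m] * t)
            counters["density_terms"] = 0
            overlap_pmf(SizedSets(sizes, n), 0)
            return counters["density_terms"]

        ops4, ops8, ops16 = ops(4), ops(8), ops(16)
        # each extra set adds one fixed-size level: growth is affine in t
        assert ops16 - ops8 == 2 * (ops8 - ops4)
        assert ops16 <= 16 * (m + 1) ** 2


class TestTail:
    def test_tail_from_zero_is_one(self):
        result = overlap_tail(SizedSets((200, 300, 400), 1000), 0)
        assert result.p == 1.0
        assert result.log10_p == 0.0

    def test_tail_above_max_overlap_is_zero(self):
        result = overlap_tail(SizedSets((3, 4, 5), 8), 4)
        assert result.p == 0.0
        assert result.log10_p == float("-inf")

    def test_tail_monotone_nonincreasing(self):
        sets = SizedSets((20, 30, 40), 100)
        tails = [overlap_tail(sets, x).p for x in range(21)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_tail_matches_exhaustive_sum(self):
        sets = SizedSets((3, 4, 5), 8)
        expected = sum(overlap_pmf_exhaustive(sets, i) for i in range(1, 4))
        assert overlap_tail(sets, 1).p == pytest.approx(float(expected), rel=1e-10)

    def test_two_set_tail_matches_scipy_survival(self):
        sets = SizedSets((30, 50), 120)
        for x in range(1, 31):
            assert overlap_tail(sets, x).p == pytest.approx(
                hypergeom.sf(x - 1, 120, 30, 50), rel=1e-9, abs=1e-300
            )

    def test_upper_and_lower_tails_are_complementary(self):
        sets = SizedSets((10, 20, 30), 100)
        for x in range(1, 11):
            upper = overlap_tail(sets, x, "upper").p
            lower = overlap_tail(sets, x - 1, "lower").p
            assert upper + lower == pytest.approx(1.0, abs=1e-9)

    def test_log10_companion_consistent_when_p_positive(self):
        result = overlap_tail(SizedSets((20, 30, 40), 200), 10)
        assert 0 < result.p <= 1
        assert abs(math.log10(result.p) - result.log10_p) < 1e-9

    def test_deep_tail_stays_representable_in_log10(self):
        # a tail deep in the subnormal range, near the underflow floor
        sizes = (125, 522, 107, 260, 137, 435)
        result = overlap_tail(SizedSets(sizes, 20687), 34)
        assert 0 <= result.p < 1e-300
        assert math.isfinite(result.log10_p)
        assert result.log10_p < -300
        # and past the floor the linear value degrades to exactly zero
        deeper = overlap_tail(SizedSets(sizes, 20687), 60)
        assert deeper.p == 0.0
        assert math.isfinite(deeper.log10_p)


class TestMoments:
    def test_two_set_expectation_is_classical(self):
        assert expected_overlap(SizedSets((8, 11), 50)) == pytest.approx(8 * 11 / 50, rel=1e-12)

    def test_full_universe_sets_expect_full_overlap(self):
        assert expected_overlap(SizedSets((40, 40), 40)) == pytest.approx(40.0, rel=1e-12)

    def test_seven_way_expected_overlap(self):
        sizes = (125, 522, 107, 260, 137, 435, 114)
        # direct product arithmetic: prod(s_i) / n^6
        direct = math.prod(sizes) / 20687**6
        assert expected_overlap(SizedSets(sizes, 20687)) == pytest.approx(direct, rel=1e-12)
        assert direct == pytest.approx(1.574e-10, rel=1e-3)

    def test_fold_enrichment_zero_iff_no_overlap(self):
        sets = SizedSets((10, 20), 100)
        assert fold_enrichment(0, sets) == 0.0
        assert fold_enrichment(2, sets) == pytest.approx(2 / 2.0, rel=1e-12)

    def test_fold_enrichment_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fold_enrichment(11, SizedSets((10, 20), 100))


class TestOracles:
    def test_naive_two_sets_collapse_to_density(self):
        assert overlap_pmf_naive(SizedSets((5, 4), 10), 2) == pytest.approx(
            math.log(100 / 210), rel=1e-12
        )

    def test_naive_rejects_many_sets(self):
        with pytest.raises(NotImplementedError):
            overlap_pmf_naive(SizedSets((2,) * 7, 10), 0)

    def test_exhaustive_pair_matches_hypergeometric(self):
        # two 2-subsets of a 4-universe share one element with P = 2/3
        sets = SizedSets((2, 2), 4)
        assert overlap_pmf_exhaustive(sets, 1) == Fraction(2, 3)
        assert overlap_pmf_two(1, 2, 2, 4) == pytest.approx(2 / 3, rel=1e-12)

    def test_exhaustive_identical_universes(self):
        assert overlap_pmf_exhaustive(SizedSets((3, 3), 3), 3) == 1

    def test_exhaustive_distribution_normalizes(self):
        sets = SizedSets((3, 4, 5), 8)
        assert sum(overlap_pmf_exhaustive(sets, x) for x in range(4)) == 1

    def test_exhaustive_budget_guard(self):
        with pytest.raises(NotImplementedError):
            overlap_pmf_exhaustive(SizedSets((20, 20), 60), 1)


def test_monte_carlo_agreement_total_variation():
    """Empirical overlap frequencies match the forward pmf (TV < 0.01)."""
    n, sizes, reps = 100, (10, 20, 30), 100_000
    rng = np.random.default_rng(20240915)
    counts = np.zeros(min(sizes) + 1, dtype=np.int64)
    chunk = 20_000
    for _ in range(reps // chunk):
        overlap = np.ones((chunk, n), dtype=bool)
        for k in sizes:
            order = np.argpartition(rng.random((chunk, n)), k, axis=1)
            member = np.zeros((chunk, n), dtype=bool)
            np.put_along_axis(member, order[:, :k], True, axis=1)
            overlap &= member
        xs = overlap.sum(axis=1)
        counts += np.bincount(xs, minlength=counts.size)[: counts.size]
    empirical = counts / reps
    sets = SizedSets(sizes, n)
    model = np.array([math.exp(overlap_pmf(sets, x)) for x in range(min(sizes) + 1)])
    tv = 0.5 * np.abs(empirical - model).sum()
    assert tv < 0.01


class TestSizedSetsValidation:
    def test_rejects_single_set(self):
        with pytest.raises(ValueError):
            SizedSets((5,), 10)

    def test_rejects_oversized_set(self):
        with pytest.raises(ValueError):
            SizedSets((11, 5), 10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            SizedSets((0, 5), 10)

    def test_max_overlap_is_smallest_size(self):
        assert SizedSets((7, 3, 5), 20).max_overlap == 3
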