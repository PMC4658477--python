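"""Exact probability model for intersections of multiple sets.

The model: ``t`` sets of fixed sizes ``s_1 .. s_t`` are drawn independently
and uniformly without replacement from a background population of ``n``
elements.  The size ``X`` of their common intersection is then a random
variable whose distribution generalizes the two-set hypergeometric law.
Conditioning on the running intersection of the first ``k`` sets — which,
given its size ``j``, is itself a uniform random ``j``-subset — yields a
chain of hypergeometric kernels

    P(X_k = i | X_{k-1} = j) = C(j, i) C(n - j, s_k - i) / C(n, s_k),

so the full pmf is a nested sum of products of hypergeometric densities.
Evaluating that sum naively costs O(m^{t-2}) terms (``m`` the smallest set
size); the forward algorithm below factorizes it level by level, reducing
the cost to O(t * m^2) while every accumulation stays in natural-log space
with log-sum-exp, so tails far below the double-precision underflow floor
(e.g. 1e-310) remain representable through their log10 companion.

Two deliberately independent oracles are provided for testing:
``overlap_pmf_naive`` evaluates the un-factorized nested sum in exact
rational arithmetic, and ``overlap_pmf_exhaustive`` counts every possible
configuration of subsets outright.  Neither shares code with the forward
path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "SizedSets",
    "ExactTestResult",
    "log_binomial",
    "overlap_pmf_two",
    "overlap_pmf",
    "overlap_tail",
    "overlap_pmf_naive",
    "overlap_pmf_exhaustive",
    "expected_overlap",
    "fold_enrichment",
]

_LOG10 = math.log(10.0)

#: running count of hypergeometric density terms evaluated by the forward
#: algorithm; used to verify the O(t * m^2) complexity claim by operation
#: counting rather than wall clock.
counters = {"density_terms": 0}


@dataclass(frozen=True)
class SizedSets:
    """Cardinalities of the sets under test plus the background size.

    Parameters
    ----------
    sizes:
        Cardinalities ``s_1 .. s_t`` of the ``t >= 2`` sets.
    n:
        Size of the background population every set is sampled from.

    The smallest cardinality ``min(sizes)`` is the maximum possible
    intersection size.
    """

    sizes: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        object.__setattr__(self, "n", int(self.n))
        if self.n < 1:
            raise ValueError(f"background size must be >= 1, got {self.n}")
        if len(self.sizes) < 2:
            raise ValueError("at least two sets are required")
        for s in self.sizes:
            if s < 1:
                raise ValueError(f"set sizes must be positive, got {s}")
            if s > self.n:
                raise ValueError(f"set size {s} exceeds background size {self.n}")

    @property
    def t(self) -> int:
        return len(self.sizes)

    @property
    def max_overlap(self) -> int:
        return min(self.sizes)


@dataclass(frozen=True)
class ExactTestResult:
    """Outcome of the exact intersection test at an observed overlap ``x``.

    ``p`` is the tail probability on the linear scale and may underflow to
    exactly 0.0; ``log10_p`` stays finite whenever the tail is
    mathematically positive and is the authoritative value for extreme
    significances.
    """

    x: int
    expected: float
    fe: float
    p: float
    log10_p: float
    alternative: str = "upper"

    # kept as aliases so the result reads naturally in either vocabulary
    @property
    def p_upper(self) -> float:
        return self.p

    @property
    def log10_p_upper(self) -> float:
        return self.log10_p


def log_binomial(n_total: int, k: int) -> float:
    """Natural log of the binomial coefficient C(n_total, k).

    Returns ``-inf`` for ``k`` outside ``[0, n_total]`` (an impossible
    draw) and is exact (0.0) at the boundaries ``k = 0`` and
    ``k = n_total``.  Computed through the log-gamma function so that very
    large coefficients never overflow.
    """
    if n_total < 0:
        raise ValueError(f"n_total must be nonnegative, got {n_total}")
    if k < 0 or k > n_total:
        return float("-inf")
    if k == 0 or k == n_total:
        return 0.0
    return float(gammaln(n_total + 1) - gammaln(k + 1) - gammaln(n_total - k + 1))


def overlap_pmf_two(x: int, a: int, b: int, n: int) -> float:
    """P(two random subsets of sizes ``a`` and ``b`` of ``n`` share exactly ``x``).

    This is the classical hypergeometric density
    ``C(a, x) C(n - a, b - x) / C(n, b)``; zero outside the support
    ``[max(0, a + b - n), min(a, b)]``.
    """
    if not (0 <= a <= n and 0 <= b <= n):
        raise ValueError(f"set sizes must lie in [0, n]; got a={a}, b={b}, n={n}")
    if x < max(0, a + b - n) or x > min(a, b):
        return 0.0
    return math.exp(log_binomial(a, x) + log_binomial(n - a, b - x) - log_binomial(n, b))


@lru_cache(maxsize=64)
def _lgamma_table(n: int) -> np.ndarray:
    """gammaln(i) for i = 0 .. n + 1, shared by all coefficients over one population."""
    table = gammaln(np.arange(n + 2, dtype=float))
    table.setflags(write=False)
    return table


def _log_dhyper_grid(i: np.ndarray, j: np.ndarray, n: int, s: int, lg: np.ndarray) -> np.ndarray:
    """Log hypergeometric density P(i hits | j marked of n, draw s), broadcast over i x j.

    ``i`` is a column vector of candidate intersection sizes, ``j`` a row
    vector of marked-subset sizes.  Invalid (out-of-support) cells are -inf.
    """
    valid = (i <= j) & (i <= s) & (s - i <= n - j)
    i_c = np.where(valid, i, 0)
    j_c = np.where(valid, j, 0)
    log_c_ji = lg[j_c + 1] - lg[i_c + 1] - lg[j_c - i_c + 1]
    rem, draw = n - j_c, s - i_c
    log_c_rest = lg[rem + 1] - lg[draw + 1] - lg[rem - draw + 1]
    log_c_ns = lg[n + 1] - lg[s + 1] - lg[n - s + 1]
    out = log_c_ji + log_c_rest - log_c_ns
    return np.where(valid, out, -np.inf)


@lru_cache(maxsize=256)
def _logpmf_table(sizes: tuple[int, ...], n: int) -> np.ndarray:
    """Log pmf of the t-way intersection size for x = 0 .. min(sizes).

    Forward pass: sets are processed in descending size order (the result
    is invariant to order); the state support at each level is bounded by
    the running minimum of the processed sizes, so it only ever shrinks.
    """
    ordered = tuple(sorted(sizes, reverse=True))
    lg = _lgamma_table(n)
    a, b = ordered[0], ordered[1]
    j = np.arange(min(a, b) + 1)
    state = _log_dhyper_grid(j[:, None], np.asarray([[a]]), n, b, lg).ravel()
    counters["density_terms"] += state.size
    for s in ordered[2:]:
        i = np.arange(min(state.size - 1, s) + 1)[:, None]
        grid = _log_dhyper_grid(i, np.arange(state.size)[None, :], n, s, lg)
        counters["density_terms"] += grid.size
        with np.errstate(invalid="ignore"):
            state = logsumexp(state[None, :] + grid, axis=1)
        state = np.where(np.isnan(state), -np.inf, state)
    state.setflags(write=False)
    return state


@lru_cache(maxsize=256)
def _log_tail_table(sizes: tuple[int, ...], n: int) -> np.ndarray:
    """log P(X >= x) for x = 0 .. min(sizes), from the forward pmf table."""
    pmf = _logpmf_table(sizes, n)
    rev = np.logaddexp.accumulate(pmf[::-1])[::-1]
    tail = np.minimum(rev, 0.0)  # guard the x = 0 entry against rounding above 1
    tail.setflags(write=False)
    return tail


def overlap_pmf(sets: SizedSets, x: int) -> float:
    """Log probability that all sets share exactly ``x`` elements.

    Computed by the forward algorithm; for ``t = 2`` this coincides with
    ``log(overlap_pmf_two)``.  Returns ``-inf`` for ``x`` above the maximum
    possible overlap.
    """
    if x < 0:
        raise ValueError(f"overlap size must be nonnegative, got {x}")
    if x > sets.max_overlap:
        return float("-inf")
    return float(_logpmf_table(tuple(sets.sizes), sets.n)[x])


def overlap_tail(sets: SizedSets, x: int, alternative: str = "upper") -> ExactTestResult:
    """Exact one-tailed test of an observed overlap of ``x`` elements.

    The default upper tail ``P(X >= x)`` measures over-representation:
    densities from ``x`` up to the maximum possible overlap ``min(sizes)``
    are summed in log space.  ``alternative='lower'`` gives the depletion
    tail ``P(X <= x)``.
    """
    if x < 0:
        raise ValueError(f"overlap size must be nonnegative, got {x}")
    if alternative not in ("upper", "lower"):
        raise ValueError(f"alternative must be 'upper' or 'lower', got {alternative!r}")
    expected = expected_overlap(sets)
    fe = x / expected if expected > 0 else float("inf") if x else 0.0
    m = sets.max_overlap
    if alternative == "upper":
        if x == 0:
            log_p = 0.0
        elif x > m:
            log_p = float("-inf")
        else:
            log_p = float(_log_tail_table(tuple(sets.sizes), sets.n)[x])
    else:
        pmf = _logpmf_table(tuple(sets.sizes), sets.n)
        log_p = 0.0 if x >= m else float(min(logsumexp(pmf[: x + 1]), 0.0))
    return ExactTestResult(
        x=x,
        expected=expected,
        fe=fe,
        p=math.exp(log_p) if log_p > -745 else 0.0,
        log10_p=log_p / _LOG10,
        alternative=alternative,
    )


def expected_overlap(sets: SizedSets) -> float:
    """Expected intersection size under independent uniform sampling: n * prod(s_i / n)."""
    value = float(sets.n)
    for s in sets.sizes:
        value *= s / sets.n
    return value


def fold_enrichment(x: int, sets: SizedSets) -> float:
    """Ratio of the observed to the expected overlap fraction.

    FE = (x / n) / prod(s_i / n) = x / expected_overlap.  Values above 1
    indicate over-representation.  Defined for ``0 <= x <= min(sizes)``
    and positive set sizes.
    """
    if any(s == 0 for s in sets.sizes):
        raise ValueError("fold enrichment is undefined when a set is empty")
    if not 0 <= x <= sets.max_overlap:
        raise ValueError(
            f"observed overlap {x} outside [0, {sets.max_overlap}] for sizes {sets.sizes}"
        )
    if x == 0:
        return 0.0
    return x / expected_overlap(sets)


# ---------------------------------------------------------------------------
# Independent oracles (exact rational arithmetic; test use only)
# ---------------------------------------------------------------------------


def _dhyper_frac(x: int, marked: int, n: int, draw: int) -> Fraction:
    if x < 0 or x > marked or draw - x < 0 or draw - x > n - marked:
        return Fraction(0)
    return Fraction(
        math.comb(marked, x) * math.comb(n - marked, draw - x), math.comb(n, draw)
    )


def overlap_pmf_naive(sets: SizedSets, x: int) -> float:
    """Log pmf by direct evaluation of the nested hypergeometric sums.

    The chain of summations over the intermediate overlap sizes (``j`` of
    the first two sets, ``k`` after the third, ...) is evaluated literally,
    without the forward-state factorization, in exact rational arithmetic.
    Exponential cost in ``t``; supported for 2 <= t <= 6 as a test oracle.
    """
    if x < 0:
        raise ValueError(f"overlap size must be nonnegative, got {x}")
    if not 2 <= sets.t <= 6:
        raise NotImplementedError("naive nested summation supports 2..6 sets only")
    sizes, n = sets.sizes, sets.n

    def nested(idx: int, j: int) -> Fraction:
        if idx == len(sizes):
            return Fraction(int(j == x))
        return sum(
            (
                _dhyper_frac(i, j, n, sizes[idx]) * nested(idx + 1, i)
                for i in range(x, min(j, sizes[idx]) + 1)
            ),
            Fraction(0),
        )

    prob = nested(1, sizes[0])
    return math.log(prob) if prob > 0 else float("-inf")


@lru_cache(maxsize=32)
def _exhaustive_distribution(sizes: tuple[int, ...], n: int) -> tuple[tuple[int, ...], int]:
    """Counts of configurations per intersection size, by full enumeration.

    Every combination of subsets of the stated sizes is generated as a
    bitmask; the popcount of the running AND is tallied.  Returns
    (counts for x = 0 .. min(sizes), total number of configurations).
    """
    total = 1
    for s in sizes:
        total *= math.comb(n, s)
    if total > 3_000_000:
        raise NotImplementedError(
            f"enumeration budget exceeded: {total} configurations"
        )
    mask_lists = [
        [sum(1 << b for b in combo) for combo in combinations(range(n), s)]
        for s in sizes
    ]
    counts = [0] * (min(sizes) + 1)

    def recurse(idx: int, inter: int) -> None:
        if idx == len(mask_lists):
            counts[inter.bit_count()] += 1
            return
        for mask in mask_lists[idx]:
            recurse(idx + 1, inter & mask)

    for mask in mask_lists[0]:
        recurse(1, mask)
    return tuple(counts), total


def overlap_pmf_exhaustive(sets: SizedSets, x: int) -> Fraction:
    """Exact probability of an overlap of ``x`` by brute-force enumeration.

    Counts, over every jointly possible configuration of subsets of the
    stated sizes, those whose common intersection has exactly ``x``
    elements; exact integer arithmetic throughout.  Feasible only for tiny
    problems (the configuration count is capped at 3e6).
    """
    if x < 0:
        raise ValueError(f"overlap size must be nonnegative, got {x}")
    counts, total = _exhaustive_distribution(tuple(sets.sizes), sets.n)
    if x >= len(counts):
        return Fraction(0)
    return Fraction(counts[x], total)
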