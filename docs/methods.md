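# Methods

## The probability model

Let a background population contain `n` distinguishable elements, and
let sets `S₁ … S_t` of fixed sizes `s₁ … s_t` each be an independent
uniform draw without replacement from that population. The object of
inference is the size `X = |S₁ ∩ … ∩ S_t|` of the common intersection.

For `t = 2` the law of `X` is the classical hypergeometric density
`C(a, x)·C(n − a, b − x)/C(n, b)`. For `t > 2` the key observation is
that, conditioned on the intersection of the first `k` sets having size
`j`, that intersection is itself a uniform random `j`-subset of the
population and is independent of the next set. The next intersection
size is therefore hypergeometric with `j` "marked" elements:

    P(X_{k+1} = i | X_k = j) = C(j, i) · C(n − j, s_{k+1} − i) / C(n, s_{k+1}).

The pmf of `X = X_t` is the resulting nested sum over all intermediate
intersection sizes — a sum of products of hypergeometric densities. The
one-tailed significance of an observed overlap `x` is
`P(X ≥ x) = Σ_{i=x}^{min(s)} P(X = i)` (over-representation); the lower
tail is available for depletion questions but the upper tail is the
default and the one used everywhere in the package's own analyses.

The fold enrichment compares the observed overlap fraction with its
expectation under the same model:

    FE = (x / n) / ∏ᵢ (sᵢ / n),      E[X] = n · ∏ᵢ (sᵢ / n).

FE is defined for `0 ≤ x ≤ min(sᵢ)` and positive set sizes, and is zero
exactly when `x = 0`.

**Assumptions.** Elements are exchangeable (no element is more likely
to be sampled than another), sets are drawn independently, and set
sizes are treated as fixed. Violations of the first two assumptions are
precisely what the simulation module quantifies.

## Forward evaluation

Evaluating the nested sum literally costs `O(m^{t-2})` terms, `m` the
smallest set size. The implementation instead runs a forward
(dynamic-programming) pass, as in hidden-Markov-model likelihood
evaluation: a state vector over the possible intersection sizes of the
sets processed so far is propagated through one hypergeometric kernel
per additional set. Each level is at most an `(m+1)²` sum, giving
`O(t·m²)` total work; a unit test verifies the affine growth of the
operation count in `t` by counting density-term evaluations rather than
timing.

Sets are processed in descending size order. The result is invariant to
order (verified by a permutation property test); descending order means
the state support — bounded by the running minimum of the processed
sizes — only ever shrinks.

Properties enforced by the test suite: normalization of the pmf,
reduction to the classical hypergeometric law at `t = 2`, permutation
invariance, tail monotonicity in `x`, agreement with two independent
oracles (below), and total-variation agreement < 0.01 with 10⁵
Monte-Carlo draws at `n = 100`, sizes (10, 20, 30).

## Numerics

All accumulation happens in natural-log space with log-sum-exp.
Binomial coefficients are computed through the log-gamma function;
`gammaln` values for `0 … n+1` are computed once per background size
and shared by every coefficient (the dominant repeated operation).
Working arithmetic is 64-bit floating point, which holds the pmf
normalization error below 10⁻⁹ across the tested range.

Linear-scale probabilities underflow near 10⁻³⁰⁸. Every result
therefore carries a `log10_p` companion that stays finite whenever the
tail is mathematically positive; the summary CSV formats P values from
the log10 value, so entries such as `1.2e-1210` print correctly, and
multiple-testing adjustment also runs on log10 values. The linear `p`
field degrades gracefully to subnormals and then exactly 0.0.

An observed `x` above `min(sizes)` is impossible under the model; the
pmf and tail return probability 0 for it (callers enumerate
combinations mechanically), while `fold_enrichment` treats it as a
domain error.

## Test oracles

Two independent implementations exist purely to check the forward path:

- **naive nested sum** (`overlap_pmf_naive`, 2 ≤ t ≤ 6): the literal
  chain of summations in exact rational arithmetic, with no
  forward-state factorization;
- **exhaustive enumeration** (`overlap_pmf_exhaustive`): every
  configuration of subsets of the stated sizes is generated as a
  bitmask and the intersection popcounts tallied, capped at 3·10⁶
  configurations.

Forward, naive and exhaustive values agree to relative 10⁻¹⁰ on the
tested configurations. The two-set case is additionally cross-checked
against `scipy.stats.hypergeom`, and Benjamini–Hochberg adjustment
against `statsmodels` where no underflow is involved; neither library
participates in the package's own computation path for the multi-set
statistic.

## Combination analysis

For `t` sets all `2^t − 1` nonempty combinations are enumerated
(refused above `t = 30`, where a different product would be needed).
The observed size of a combination is its **total** overlap — elements
common to every selected set, regardless of membership in unselected
sets — which is the quantity the probability model describes. Exclusive
Venn-style region counts are available for display but carry no P
value. Degree-1 records are listed for plotting but never tested; a
single set has no overlap hypothesis.

The multiple-testing family is always the complete set of degree ≥ 2
combinations, `M = 2^t − t − 1`, even when the user displays only some
degrees — so a 7-set analysis multiplies by 120 under Bonferroni
regardless of filtering. Benjamini–Hochberg is the standard step-up
over the same family, computed on log10 values. Element lists are
retained per record up to a 10,000-element cap to bound memory.

Summary tables are written with fixed column order, deterministic
formatting and a stable sort (ties always broken by the combination
barcode), so identical inputs produce byte-identical CSV.

## The weighted-sampling robustness study

To probe the independence assumption, the simulator designates
`n_pref` "preferential" elements (default 100) that are `w ≥ 1` times
more likely to be sampled than the rest — a simple model of elements
that tend to be selected together. Defaults follow the reference
design: three sets of sizes 200, 300, 400, a significance threshold of
0.05, and 1000 replicates per cell. Each replicate draws the sets by
weighted sampling without replacement, computes the exact upper-tail P
of the overlap among **all** sets, and the false-positive rate is the
fraction of replicates with `P < α`, reported with a 95% Wilson
interval.

Weighted sampling without replacement is defined sequentially: each
successive draw picks an element with probability proportional to the
weights of those remaining. The implementation realizes this through
the exponential-race equivalence — give element `i` an independent
`Exp(wᵢ)` clock and keep the `k` earliest — which is distributionally
identical to the sequential procedure and vectorizes. At `w = 1` it
reduces to uniform sampling, verified by a goodness-of-fit test.

Because the p-value of a discrete test is itself discrete, the true
rejection probability at `α = 0.05` is the largest attainable tail
value below α, computable exactly from the model (e.g. 0.0459 for
sizes 200/300/400 at `n = 1000`); it is never above α under unbiased
sampling, and the suite checks the empirical rate against that bound
across population sizes. Replicate randomness is spawned as
deterministic substreams of the experiment seed, so results are exactly
reproducible and replicates could be parallelized without changing
them.

## The synthetic fixture generator

`make_fixture_collection` builds collections with exactly known ground
truth. With no planted overlaps, every set is an independent uniform
draw — the null model of the exact test, which is what the calibration
tests sample. With planted overlaps, each planted combination receives
a dedicated element block (super-combination blocks counting toward
their sub-combinations) and remaining members are filled from elements
used by no other set, so every planted total is reproduced exactly by
`count_overlap`. The price of that exactness is that non-planted
combinations of a planted fixture have deterministic (block-implied)
overlaps rather than random ones; tests that need null randomness use
unplanted fixtures. Infeasible plants (blocks exceeding a set's size or
the population) are rejected with the violated budget named.

What the generator does **not** emulate: real gene lists have
correlated membership (pathway structure, study ascertainment), unequal
element "visibility" across studies, and identifier noise. Passing
tests on these fixtures validate the combinatorics and calibration of
the test under its stated assumptions, not robustness to those
real-data features — that is exactly what the weighted-sampling study
probes, one violation at a time.

## Visualization conventions

Bar heights in the matrix and circular layouts are exactly proportional
to observed intersection sizes (asserted on the rendered artists). Fill
intensity is a monotone function of −log10(adjusted P), capped at a
configurable ceiling (default 10) so astronomically small P values do
not flatten the palette; records without a P value render neutral grey.
The circular layout starts at 12 o'clock and runs clockwise in sort
order. Pairwise heatmap and network color by the Bonferroni-adjusted
pairwise P over the full degree ≥ 2 family, keeping them consistent
with the exhaustive analysis. Output defaults to SVG with a fixed hash
salt and no embedded date, so re-rendering the same specification is
byte-identical; the network layout takes an explicit seed.

## Problem sizes and runtime

The package's own analyses and tests run at the reference scales: the
seven-census example at `n = 20,687` with smallest set size 107
(forward tables of a few hundred entries — milliseconds), simulation
cells at 1000 replicates for populations up to 10,000 (seconds per
cell), Monte-Carlo pmf validation at 10⁵ draws, and calibration checks
at 500 replicates. The full test suite completes in well under a
minute on one core.

## Known limitations

- The main path is fixed-precision (64-bit); tails are exact in log
  space to ~10⁻¹⁰ relative accuracy, not arbitrary precision. The
  rational-arithmetic oracles are exponential-cost and only for tiny
  problems.
- Exhaustive combination analysis is capped at 30 sets; beyond that the
  2^t enumeration itself, not the per-combination test, is the barrier.
- The model treats set sizes as fixed and elements as exchangeable;
  P values under strong sampling bias in small populations are
  anti-conservative, as the simulation study quantifies.
- No approximation modes (Poisson/binomial) are offered; the exact
  computation is fast enough for the intended range.
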