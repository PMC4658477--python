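# exactsets

Exact statistical tests and scalable visualization of multi-set
intersections.

## The problem

Comparing two gene lists against a background of all genes is routine:
the overlap of two independently, uniformly drawn subsets follows the
hypergeometric distribution and Fisher's exact test gives its
significance. But many questions involve **more than two** sets — seven
independently curated cancer gene censuses, six GWAS trait gene sets,
any panel of signatures — and the distribution of the common
intersection of three or more random subsets is no longer a textbook
object. Simulation gives only rough estimates and breaks down exactly
where you need it most: huge backgrounds, small expected overlaps.

`exactsets` computes the distribution **exactly**. Given `t` sets of
sizes `s₁ … s_t` drawn independently and uniformly without replacement
from a background of `n` elements, the intersection size `X` satisfies a
chain of hypergeometric laws: conditioned on the running intersection of
the first `k` sets having size `j`, the next set meets it in `i`
elements with probability

```
P(i | j) = C(j, i) · C(n − j, s_{k+1} − i) / C(n, s_{k+1})
```

so `P(X = x)` is a nested sum of products of hypergeometric densities.
A forward (dynamic-programming) pass evaluates it in `O(t·m²)` time
(`m` = smallest set size) instead of the exponential cost of the naive
sum, entirely in log space, so tails far below the floating-point
underflow floor (10⁻³⁰⁰ and beyond) remain usable through their log10
value. Alongside the one-tailed probability `P(X ≥ x)` the package
reports the **fold enrichment**

```
FE = (x/n) / ∏ᵢ (sᵢ/n),
```

the ratio of the observed to the expected overlap fraction.

On top of the core test sit:

- **set handling** — GMT and one-set-per-column TSV/CSV input, explicit
  or size-only background universes with strict membership checks;
- **combination analysis** — all `2^t − 1` combinations enumerated, each
  degree ≥ 2 combination tested, Bonferroni or Benjamini–Hochberg
  adjustment performed in log space;
- **robustness simulation** — a weighted-sampling experiment measuring
  the false-positive rate when the uniform-sampling assumption is
  violated;
- **visualization** — matrix-layout (UpSet-style) and circular
  multi-track intersection plots, pairwise significance heatmaps and
  networks, all deterministic vector output.

## Worked example

Seven cancer gene censuses of sizes 125, 522, 107, 260, 137, 435 and
114 genes, each treated as a draw from the 20,687 protein-coding human
genes, share 9 genes:

```python
from exactsets import SizedSets, overlap_tail

sets = SizedSets(sizes=(125, 522, 107, 260, 137, 435, 114), n=20687)
result = overlap_tail(sets, x=9)
```

prints (see `examples/exact_test_from_sizes.py`):

```
expected overlap : 1.574e-10
fold enrichment  : 5.720e+10
P(X >= 9)        : 3.582e-95
log10 P          : -94.446
```

Under independent sampling, fewer than 2·10⁻¹⁰ genes are expected in
the 7-way intersection, so 9 shared genes is a ~5.7·10¹⁰-fold
enrichment; Bonferroni-adjusted over the 120 combinations of degree ≥ 2
the tail probability is ≈ 4.3·10⁻⁹³ — the consensus cannot be chance.

The same machinery from the shell:

```bash
exactsets test --sizes 125,522,107,260,137,435,114 --n 20687 --x 9
exactsets analyze --gmt sets.gmt --background-size 20687 \
    --min-degree 2 --sort-by size --plot matrix --out-dir results/
exactsets simulate --n 1000,10000 --w 1.0,2.0 --reps 1000 --seed 1
```

Other entry points, one short script each, live in `examples/`:
full combination analysis of a synthetic collection
(`analyze_collection.py`), the weighted-sampling false-positive-rate
study (`simulate_false_positives.py`), and all four plot layouts
(`plot_gallery.py`).

## Documentation

The model, its assumptions, numerical choices and known limitations are
described in `docs/methods.md`.
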