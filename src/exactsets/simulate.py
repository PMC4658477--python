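"""Type-I-error simulation under weighted sampling, and synthetic fixtures.

The exact test assumes every set is an unbiased uniform sample from the
background.  This module probes what happens when that assumption fails:
a block of "preferential" elements carries a sampling weight ``w >= 1``
relative to the rest, mimicking dependent membership (elements that tend
to be selected together).  For each replicate, the sets are drawn by
weighted sampling without replacement, the exact upper-tail P of the
full overlap among all sets is computed, and the false-positive rate is
the fraction of replicates significant at ``alpha``.

Weighted sampling without replacement follows the sequential-draw scheme:
each successive element is chosen with probability proportional to the
weights of the elements still available.  It is realized here through the
exponential-race equivalence (draw an Exp(w_i) clock per element and keep
the k earliest), which yields exactly the same distribution as the
sequential procedure while vectorizing cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .exact import _log_tail_table
from .sets import SetCollection

__all__ = [
    "SimulationConfig",
    "weighted_sample",
    "fpr_experiment",
    "fpr_grid",
    "make_fixture_collection",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one false-positive-rate experiment.

    Defaults follow the reference design: three sets of sizes 200, 300 and
    400, 100 preferential elements, 1000 replicates, significance
    threshold 0.05.
    """

    n: int
    set_sizes: tuple[int, ...] = (200, 300, 400)
    n_pref: int = 100
    weight: float = 1.0
    reps: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_sizes", tuple(int(s) for s in self.set_sizes))
        if self.n_pref > self.n:
            raise ConfigurationError("n_pref cannot exceed the population size")
        if any(s > self.n for s in self.set_sizes):
            raise ConfigurationError("set sizes cannot exceed the population size")
        if self.weight < 1.0:
            raise ConfigurationError("weight must be >= 1")
        if self.reps < 1:
            raise ConfigurationError("at least one replicate is required")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")


def weighted_sample(
    n: int, n_pref: int, w: float, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``k`` distinct indices from ``range(n)`` without replacement.

    The first ``n_pref`` indices carry weight ``w``, the rest weight 1;
    each sequential draw is proportional to the remaining weights.
    Implemented by the exponential race: index i with clock Exp(w_i), keep
    the k earliest, which is distributionally identical to sequential
    draws.  Returns the sampled indices (unordered).
    """
    if k > n:
        raise ValueError(f"cannot draw {k} distinct elements from {n}")
    if k == n:
        return np.arange(n)
    clocks = rng.exponential(size=n)
    if w != 1.0:
        clocks[:n_pref] /= w
    return np.argpartition(clocks, k)[:k]


def _log_alpha_threshold(sizes: tuple[int, ...], n: int, alpha: float) -> np.ndarray:
    """Boolean, per overlap size x: is the exact upper-tail P < alpha?"""
    tail = _log_tail_table(tuple(sorted(sizes, reverse=True)), n)
    return tail < math.log(alpha)


def fpr_experiment(config: SimulationConfig) -> dict:
    """Empirical false-positive rate of the full-overlap exact test.

    Each replicate draws the sets independently by weighted sampling,
    counts the overlap among all of them and tests it at
    ``config.alpha`` (one-tailed, upper).  Returns the rate, its 95%
    Wilson interval and the replicate count.  Replicate substreams are
    spawned deterministically from the seed, so the result is exactly
    reproducible.
    """
    sizes, n = config.set_sizes, config.n
    significant = _log_alpha_threshold(sizes, n, config.alpha)
    streams = np.random.SeedSequence(config.seed).spawn(config.reps)
    hits = 0
    for stream in streams:
        rng = np.random.default_rng(stream)
        membership = np.zeros(n, dtype=np.int8)
        for k in sizes:
            membership[weighted_sample(n, config.n_pref, config.weight, k, rng)] += 1
        x = int(np.count_nonzero(membership == len(sizes)))
        if significant[x]:
            hits += 1
    fpr = hits / config.reps
    low, high = _wilson_interval(hits, config.reps)
    return {"fpr": fpr, "ci95": (low, high), "reps": config.reps, "hits": hits}


def _wilson_interval(hits: int, total: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = hits / total
    denom = 1 + z**2 / total
    center = (p + z**2 / (2 * total)) / denom
    half = z * math.sqrt(p * (1 - p) / total + z**2 / (4 * total**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def fpr_grid(
    weights: list[float],
    populations: list[int],
    base: SimulationConfig,
) -> "pd.DataFrame":
    """Run ``fpr_experiment`` over a (weight, population-size) grid.

    Each cell gets its own deterministic sub-seed derived from
    ``base.seed`` and the cell coordinates, so adding rows or columns does
    not perturb existing cells.
    """
    import pandas as pd
    from dataclasses import replace

    rows = []
    for w in weights:
        for n in populations:
            cell_seed = int(
                np.random.SeedSequence([base.seed, int(round(w * 1000)), n]).generate_state(1)[0]
                % 2**31
            )
            config = replace(base, n=n, weight=float(w), seed=cell_seed)
            result = fpr_experiment(config)
            rows.append(
                {
                    "weight": w,
                    "n": n,
                    "fpr": result["fpr"],
                    "ci95_low": result["ci95"][0],
                    "ci95_high": result["ci95"][1],
                    "reps": result["reps"],
                }
            )
    return pd.DataFrame(rows)


def make_fixture_collection(
    n: int,
    sizes: list[int],
    planted: dict[tuple[str, ...] | str, int] | None = None,
    seed: int = 0,
    names: list[str] | None = None,
) -> SetCollection:
    """Build a synthetic collection with exactly known intersection counts.

    Elements are ``e1 .. en``.  ``planted`` maps combinations of set names
    (tuples, or strings of single-character names) to the required *total*
    overlap of that combination.  Each planted combination receives a
    dedicated block of elements; blocks for super-combinations count
    toward their sub-combinations, so e.g. planting {ABC: 2, AB: 5} puts
    2 elements in A&B&C and 3 more in A&B only.  When anything is
    planted, remaining members are filled with draws from elements used
    by no other set, so no accidental overlap can perturb the planted
    counts and ``count_overlap`` reproduces every planted count exactly.
    With no plant at all, each set is an independent uniform draw from
    the population (the null model of the exact test).
    """
    if names is None:
        if len(sizes) > 26:
            names = [f"S{i + 1}" for i in range(len(sizes))]
        else:
            names = [chr(ord("A") + i) for i in range(len(sizes))]
    if len(names) != len(sizes):
        raise ConfigurationError("names and sizes must have equal length")
    plant: dict[frozenset[str], int] = {}
    for combo, count in (planted or {}).items():
        key = frozenset(combo) if not isinstance(combo, str) else frozenset(combo)
        unknown = key - set(names)
        if unknown:
            raise ConfigurationError(f"planted combination names unknown: {sorted(unknown)}")
        if len(key) < 2:
            raise ConfigurationError("planted combinations need at least two sets")
        plant[key] = int(count)

    # convert total overlaps to exclusive block sizes, largest degree first
    blocks: dict[frozenset[str], int] = {}
    for combo in sorted(plant, key=lambda c: -len(c)):
        extra = plant[combo] - sum(
            size for other, size in blocks.items() if other > combo
        )
        if extra < 0:
            raise ConfigurationError(
                f"planted count {plant[combo]} for {sorted(combo)} is below the "
                f"{plant[combo] - extra} already implied by its super-combinations"
            )
        blocks[combo] = extra

    per_set_planted = {name: 0 for name in names}
    for combo, size in blocks.items():
        for name in combo:
            per_set_planted[name] += size
    for name, size in zip(names, sizes):
        if per_set_planted[name] > size:
            raise ConfigurationError(
                f"set {name} of size {size} cannot hold {per_set_planted[name]} "
                "planted elements"
            )
    fill_budget = sum(s - per_set_planted[nm] for nm, s in zip(names, sizes))
    total_blocks = sum(blocks.values())
    if blocks and total_blocks + fill_budget > n:
        raise ConfigurationError(
            f"infeasible plant: {total_blocks} block elements plus {fill_budget} "
            f"disjoint fill elements exceed the population of {n}"
        )

    rng = np.random.default_rng(seed)
    if not blocks:
        members_ind = {
            name: frozenset(f"e{i + 1}" for i in rng.choice(n, size=size, replace=False))
            for name, size in zip(names, sizes)
        }
        return SetCollection(list(names), members_ind, n)
    pool = [f"e{i + 1}" for i in rng.permutation(n)]
    members: dict[str, set[str]] = {name: set() for name in names}
    cursor = 0
    for combo, size in blocks.items():
        chunk = pool[cursor : cursor + size]
        cursor += size
        for name in combo:
            members[name].update(chunk)
    for name, size in zip(names, sizes):
        need = size - len(members[name])
        members[name].update(pool[cursor : cursor + need])
        cursor += need
    return SetCollection(list(names), {k: frozenset(v) for k, v in members.items()}, n)
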