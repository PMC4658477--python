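"""Scalable visualizations of multi-set intersection statistics.

Four layouts are offered: a matrix-layout bar chart (UpSet-style dot
matrix below bars), a circular multi-track plot, a pairwise significance
heatmap and a pairwise network.  Bar height is always proportional to the
observed intersection size and fill intensity encodes -log10 of the
adjusted P value, capped at a configurable ceiling so astronomically
small P values do not flatten the palette.  Degree-1 records (no overlap
hypothesis, hence no P) render in neutral grey.

All functions return the matplotlib Figure; when an output path is given
the figure is also saved.  Vector output (SVG/PDF) is the default and is
rendered deterministically (fixed SVG hash salt, no embedded date) so
geometric invariants are testable byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.colors import Normalize

from .analysis import IntersectionRecord, sort_records
from .exact import SizedSets, overlap_tail
from .sets import SetCollection, count_overlap

__all__ = [
    "PlotSpec",
    "plot_matrix",
    "plot_circular",
    "plot_pairwise_heatmap",
    "plot_network",
]

_NEUTRAL = (0.75, 0.75, 0.75, 1.0)


@dataclass
class PlotSpec:
    """What to draw and how.

    ``set_names``/``set_sizes`` describe the full collection the records
    came from (row labels and side annotations); ``degree_range`` filters
    the combinations shown; ``color_cap`` is the -log10(adjusted P) value
    at which the color scale saturates.
    """

    records: list[IntersectionRecord]
    set_names: list[str]
    set_sizes: list[int]
    sort_by: str = "size"
    degree_range: tuple[int, int] | None = None
    color_cap: float = 10.0
    cmap: str = "Reds"
    output_path: str | Path | None = None
    format: str | None = None


def _select(spec: PlotSpec) -> list[IntersectionRecord]:
    records = spec.records
    if spec.degree_range is not None:
        lo, hi = spec.degree_range
        records = [r for r in records if lo <= r.degree <= hi]
    if not records:
        raise ValueError("no records to plot after degree filtering")
    return sort_records(records, key=spec.sort_by)


def _bar_color(record: IntersectionRecord, spec: PlotSpec):
    if record.log10_p_adjusted is None:
        return _NEUTRAL
    intensity = min(-record.log10_p_adjusted, spec.color_cap)
    # keep the lowest intensities visibly tinted rather than white
    norm = Normalize(vmin=-0.25 * spec.color_cap, vmax=spec.color_cap, clip=True)
    return plt.get_cmap(spec.cmap)(norm(intensity))


def _save(fig, spec: PlotSpec) -> None:
    if spec.output_path is None:
        return
    path = Path(spec.output_path)
    fmt = spec.format or (path.suffix.lstrip(".") or "svg")
    with plt.rc_context({"svg.hashsalt": "exactsets"}):
        metadata = {"Date": None} if fmt == "svg" else None
        fig.savefig(path, format=fmt, metadata=metadata)


def plot_matrix(spec: PlotSpec):
    """Matrix-layout bar chart: bars of intersection size over a dot matrix.

    The bottom panel shows one row per set and one column per combination,
    with filled markers for member sets and empty markers otherwise; set
    sizes are printed at the right.  The top panel bars are labelled with
    the observed sizes and filled by significance.
    """
    records = _select(spec)
    t = len(spec.set_names)
    ncol = len(records)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2,
        1,
        figsize=(max(6.0, 0.28 * ncol + 2.0), 5.5),
        height_ratios=[3.0, 1.2],
        sharex=True,
    )
    xs = np.arange(ncol)
    heights = [r.observed for r in records]
    colors = [_bar_color(r, spec) for r in records]
    ax_bar.bar(xs, heights, color=colors, edgecolor="black", linewidth=0.4)
    for x, h in zip(xs, heights):
        ax_bar.text(x, h, str(h), ha="center", va="bottom", fontsize=7, rotation=90)
    ax_bar.set_ylabel("intersection size")
    ax_bar.spines[["top", "right"]].set_visible(False)

    for row in range(t):
        for col, record in enumerate(records):
            filled = record.barcode[row] == "1"
            ax_dot.plot(
                col,
                t - 1 - row,
                "o",
                markersize=5,
                markerfacecolor="forestgreen" if filled else "white",
                markeredgecolor="black",
                markeredgewidth=0.5,
            )
    ax_dot.set_yticks(range(t))
    ax_dot.set_yticklabels(reversed(spec.set_names), fontsize=8)
    for row, size in enumerate(spec.set_sizes):
        ax_dot.text(ncol - 0.2, t - 1 - row, str(size), fontsize=7, va="center")
    ax_dot.set_xticks([])
    ax_dot.set_ylim(-0.7, t - 0.3)
    ax_dot.set_xlim(-0.7, ncol + 0.9)
    for spine in ax_dot.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    _save(fig, spec)
    return fig


def plot_circular(spec: PlotSpec):
    """Circular multi-track plot: one ring per set, an outer bar ring on top.

    Each angular sector is one combination (starting at 12 o'clock,
    clockwise, in sort order); a sector's block on ring i is colored when
    set i belongs to the combination and grey otherwise.  Outer bars are
    proportional to the observed size and filled by significance, with the
    size printed outside.
    """
    records = _select(spec)
    t = len(spec.set_names)
    nsec = len(records)
    fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    width = 2 * math.pi / nsec
    theta = np.arange(nsec) * width + width / 2
    track_colors = plt.get_cmap("tab10")
    inner, ring_h = 1.0, 0.35
    for row in range(t):
        bottoms = inner + row * ring_h
        face = [
            track_colors(row % 10) if r.barcode[row] == "1" else (0.88, 0.88, 0.88, 1.0)
            for r in records
        ]
        ax.bar(
            theta,
            [ring_h * 0.9] * nsec,
            width=width * 0.95,
            bottom=bottoms,
            color=face,
            linewidth=0,
        )
    base = inner + t * ring_h + 0.15
    max_obs = max(r.observed for r in records) or 1
    bar_scale = 1.6 / max_obs
    ax.bar(
        theta,
        [r.observed * bar_scale for r in records],
        width=width * 0.9,
        bottom=base,
        color=[_bar_color(r, spec) for r in records],
        edgecolor="black",
        linewidth=0.3,
    )
    for angle, r in zip(theta, records):
        ax.text(
            angle,
            base + r.observed * bar_scale + 0.12,
            str(r.observed),
            fontsize=6,
            ha="center",
            va="center",
        )
    ax.set_ylim(0, base + 1.6 + 0.5)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.spines["polar"].set_visible(False)
    for row, (name, size) in enumerate(zip(spec.set_names, spec.set_sizes)):
        ax.text(
            0.0,
            inner + row * ring_h + ring_h / 2,
            f"{name} ({size})",
            fontsize=7,
            ha="center",
            va="center",
        )
    fig.tight_layout()
    _save(fig, spec)
    return fig


def _pairwise_records(collection: SetCollection) -> list[IntersectionRecord]:
    """Degree-2 records with Bonferroni adjustment over the full family.

    The family size is 2^t - t - 1 (every combination of degree >= 2 of
    the collection) to stay consistent with the exhaustive analysis even
    though only the pairs are rendered.
    """
    t = collection.t
    n = collection.background_size
    family = 2**t - t - 1
    records = []
    for i in range(t):
        for j in range(i + 1, t):
            pair = (collection.names[i], collection.names[j])
            observed = count_overlap(collection, pair)
            result = overlap_tail(SizedSets(collection.sizes(pair), n), observed)
            barcode = "".join("1" if k in (i, j) else "0" for k in range(t))
            records.append(
                IntersectionRecord(
                    barcode=barcode,
                    sets=pair,
                    degree=2,
                    observed=observed,
                    expected=result.expected,
                    fe=result.fe,
                    p_raw=result.p,
                    log10_p_raw=result.log10_p,
                    p_adjusted=min(1.0, result.p * family),
                    log10_p_adjusted=min(0.0, result.log10_p + math.log10(family)),
                )
            )
    return records


def plot_pairwise_heatmap(
    collection: SetCollection,
    color_cap: float = 10.0,
    cmap: str = "Reds",
    output_path: str | Path | None = None,
):
    """Symmetric t x t heatmap of pairwise intersection significance.

    Off-diagonal cell (i, j) is colored by -log10 of the Bonferroni
    adjusted P of the pairwise exact test (capped); the diagonal is
    annotated with the set sizes.
    """
    t = collection.t
    records = _pairwise_records(collection)
    grid = np.zeros((t, t))
    index = {name: k for k, name in enumerate(collection.names)}
    for r in records:
        i, j = index[r.sets[0]], index[r.sets[1]]
        value = min(-r.log10_p_adjusted, color_cap)
        grid[i, j] = grid[j, i] = value
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * t, 1.0 + 0.6 * t))
    image = ax.imshow(grid, cmap=cmap, vmin=0.0, vmax=color_cap)
    ax.set_xticks(range(t), collection.names, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(t), collection.names, fontsize=8)
    for k, size in enumerate(collection.sizes()):
        ax.text(k, k, str(size), ha="center", va="center", fontsize=8)
    fig.colorbar(image, ax=ax, shrink=0.8, label="-log10 adjusted P")
    fig.tight_layout()
    spec = PlotSpec(records, collection.names, list(collection.sizes()), output_path=output_path)
    _save(fig, spec)
    return fig, grid


def plot_network(
    collection: SetCollection,
    color_cap: float = 10.0,
    cmap: str = "Reds",
    seed: int = 0,
    output_path: str | Path | None = None,
):
    """Pairwise intersection network.

    One node per set with area proportional to log set size; one edge per
    pair with nonzero overlap, edge width proportional to the overlap size
    and edge color intensity to -log10 of the adjusted P.  Node placement
    uses a spring layout with a fixed seed, so coordinates are
    deterministic.
    """
    records = _pairwise_records(collection)
    graph = nx.Graph()
    for name, size in zip(collection.names, collection.sizes()):
        graph.add_node(name, size=size)
    for r in records:
        if r.observed > 0:
            graph.add_edge(
                r.sets[0],
                r.sets[1],
                overlap=r.observed,
                neg_log10_p=min(-r.log10_p_adjusted, color_cap),
            )
    pos = nx.spring_layout(graph, seed=seed)
    fig, ax = plt.subplots(figsize=(6, 6))
    node_area = [240.0 * math.log10(max(graph.nodes[v]["size"], 2)) for v in graph.nodes]
    nx.draw_networkx_nodes(
        graph, pos, ax=ax, node_size=node_area, node_color="lightsteelblue", edgecolors="black"
    )
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=8)
    if graph.number_of_edges():
        overlaps = np.array([d["overlap"] for _, _, d in graph.edges(data=True)], dtype=float)
        widths = 0.5 + 4.0 * overlaps / overlaps.max()
        intensities = [d["neg_log10_p"] for _, _, d in graph.edges(data=True)]
        nx.draw_networkx_edges(
            graph,
            pos,
            ax=ax,
            width=widths,
            edge_color=intensities,
            edge_cmap=plt.get_cmap(cmap),
            edge_vmin=0.0,
            edge_vmax=color_cap,
        )
    ax.set_axis_off()
    fig.tight_layout()
    spec = PlotSpec(records, collection.names, list(collection.sizes()), output_path=output_path)
    _save(fig, spec)
    return fig, graph, pos
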