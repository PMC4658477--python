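"""Render all four intersection visualizations for a synthetic collection.

Writes matrix.svg, circular.svg, heatmap.svg and network.svg into
./gallery/ and prints what each shows.
"""

from pathlib import Path

from exactsets import (
    PlotSpec,
    analyze,
    make_fixture_collection,
    plot_circular,
    plot_matrix,
    plot_network,
    plot_pairwise_heatmap,
)

out = Path("gallery")
out.mkdir(exist_ok=True)

collection = make_fixture_collection(
    n=5000,
    sizes=[150, 200, 250, 180, 120],
    planted={("A", "B", "C"): 20, ("B", "C", "D"): 15, ("D", "E"): 30},
    seed=7,
)
records = analyze(collection)

spec = PlotSpec(
    records,
    collection.names,
    list(collection.sizes()),
    sort_by="size",
    degree_range=(2, 5),
    output_path=out / "matrix.svg",
)
plot_matrix(spec)

spec.output_path = out / "circular.svg"
plot_circular(spec)

plot_pairwise_heatmap(collection, output_path=out / "heatmap.svg")
plot_network(collection, seed=1, output_path=out / "network.svg")

print(f"wrote {sorted(p.name for p in out.glob('*.svg'))} to {out}/")
print("matrix : bars = intersection sizes over a membership dot matrix")
print("circular: one ring per set, outer bars = sizes, color = significance")
print("heatmap: pairwise -log10 adjusted P, set sizes on the diagonal")
print("network: nodes = sets (area ~ log size), edges = overlapping pairs")
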