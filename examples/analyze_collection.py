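"""Full combination analysis of a small synthetic collection.

Builds four sets with exactly known planted overlaps, enumerates all
2^4 - 1 = 15 combinations, tests every degree >= 2 combination and
prints the most significant ones.
"""

from exactsets import analyze, make_fixture_collection, sort_records

collection = make_fixture_collection(
    n=2000,
    sizes=[80, 100, 120, 60],
    planted={("A", "B", "C"): 12, ("A", "B"): 25, ("C", "D"): 15},
    seed=42,
)

records = sort_records(analyze(collection, adjust="bonferroni"), key="p_value")

print(f"{'combination':<16}{'obs':>5}{'expected':>11}{'FE':>9}{'adj P':>12}")
for r in records[:6]:
    if r.degree < 2:
        continue
    print(
        f"{r.label:<16}{r.observed:>5}{r.expected:>11.3g}{r.fe:>9.1f}"
        f"{r.p_adjusted:>12.2e}"
    )

# Planted combinations surface with large fold enrichments (observed
# far above the product-of-fractions expectation) and tiny adjusted P;
# unplanted combinations stay near their null expectation.
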