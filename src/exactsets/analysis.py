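"""Enumeration and exact testing of every set combination.

For ``t`` sets there are ``2^t - 1`` nonempty combinations, of which
``2^t - t - 1`` have degree >= 2 and carry an overlap hypothesis.  Each
degree >= 2 combination is tested with the exact upper-tail probability of
its observed (total, non-exclusive) intersection, given the combination's
set sizes and the shared background.  The multiple-testing family is
always the full set of degree >= 2 combinations of the collection, even
when only a subset of degrees is displayed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError
from .exact import SizedSets, overlap_tail
from .sets import SetCollection, intersection_elements

__all__ = [
    "IntersectionRecord",
    "analyze",
    "adjust_pvalues",
    "sort_records",
    "write_summary",
]

#: records keep at most this many identifiers to bound memory
DEFAULT_ELEMENT_CAP = 10_000


@dataclass
class IntersectionRecord:
    """One combination of sets with its intersection statistics.

    ``barcode`` marks membership of each set (position i <-> i-th set
    name).  Statistics are ``None`` for degree-1 records: a single set has
    no overlap hypothesis but is still listed for plotting.
    """

    barcode: str
    sets: tuple[str, ...]
    degree: int
    observed: int
    expected: float | None = None
    fe: float | None = None
    p_raw: float | None = None
    log10_p_raw: float | None = None
    p_adjusted: float | None = None
    log10_p_adjusted: float | None = None
    elements: tuple[str, ...] | None = None

    @property
    def label(self) -> str:
        return " & ".join(self.sets)


def analyze(
    collection: SetCollection,
    min_degree: int = 1,
    adjust: str | None = "bonferroni",
    element_cap: int = DEFAULT_ELEMENT_CAP,
) -> list[IntersectionRecord]:
    """Test every combination of the collection's sets.

    Returns one record per combination with degree >= ``min_degree``, in
    enumeration (barcode) order.  Degree >= 2 records carry the expected
    overlap, fold enrichment and exact upper-tail P of the observed
    intersection; adjusted P values use ``adjust`` ('bonferroni', 'bh', or
    None to skip) over the family of all degree >= 2 combinations.
    """
    t = collection.t
    if t < 2:
        raise ConfigurationError("at least two sets are required")
    if t > 30:
        raise ConfigurationError(
            f"{t} sets would enumerate 2^{t} combinations; this exhaustive "
            "analysis is limited to 30 sets"
        )
    n = collection.background_size  # raises ConfigurationError if unset
    names = collection.names
    records: list[IntersectionRecord] = []
    for mask in range(1, 2**t):
        picked = tuple(names[i] for i in range(t) if mask >> i & 1)
        barcode = "".join("1" if mask >> i & 1 else "0" for i in range(t))
        degree = len(picked)
        shared = intersection_elements(collection, picked)
        record = IntersectionRecord(
            barcode=barcode,
            sets=picked,
            degree=degree,
            observed=len(shared),
            elements=tuple(sorted(shared)) if len(shared) <= element_cap else None,
        )
        if degree >= 2:
            result = overlap_tail(SizedSets(collection.sizes(picked), n), len(shared))
            record.expected = result.expected
            record.fe = result.fe
            record.p_raw = result.p
            record.log10_p_raw = result.log10_p
        records.append(record)
    if adjust is not None:
        adjust_pvalues(records, method=adjust)
    if min_degree > 1:
        records = [r for r in records if r.degree >= min_degree]
    return records


def adjust_pvalues(
    records: list[IntersectionRecord], method: str = "bonferroni"
) -> list[IntersectionRecord]:
    """Attach multiple-testing-adjusted P values (in place; records returned).

    The family is every record with degree >= 2 (size ``M``).  Bonferroni
    multiplies by ``M``; 'bh' is the Benjamini–Hochberg step-up.  All
    arithmetic runs on log10 P so adjustment survives linear-scale
    underflow.
    """
    tested = [r for r in records if r.degree >= 2]
    if not tested:
        return records
    for r in tested:
        if r.log10_p_raw is None:
            raise ConfigurationError("records must carry raw P values before adjustment")
    m = len(tested)
    if method == "bonferroni":
        shift = math.log10(m)
        for r in tested:
            r.log10_p_adjusted = min(0.0, r.log10_p_raw + shift)
            r.p_adjusted = 10.0**r.log10_p_adjusted
    elif method == "bh":
        order = sorted(tested, key=lambda r: (r.log10_p_raw, r.barcode))
        running = 0.0  # log10 of the step-up minimum, capped at 1
        for rank in range(m, 0, -1):
            r = order[rank - 1]
            running = min(running, r.log10_p_raw + math.log10(m / rank))
            r.log10_p_adjusted = min(0.0, running)
            r.p_adjusted = 10.0**r.log10_p_adjusted
    else:
        raise ConfigurationError(f"unknown adjustment method {method!r}")
    return records


_SORT_KEYS = ("size", "degree", "p_value", "set_order")


def sort_records(records: list[IntersectionRecord], key: str = "size") -> list[IntersectionRecord]:
    """Stable sort of records; ties always broken by barcode.

    'size': largest observed intersection first; 'degree': low to high;
    'p_value': most significant adjusted P first (untested records last);
    'set_order': barcode lexicographic.
    """
    if key == "size":
        return sorted(records, key=lambda r: (-r.observed, r.barcode))
    if key == "degree":
        return sorted(records, key=lambda r: (r.degree, r.barcode))
    if key == "p_value":
        return sorted(
            records,
            key=lambda r: (
                r.log10_p_adjusted if r.log10_p_adjusted is not None else math.inf,
                r.barcode,
            ),
        )
    if key == "set_order":
        return sorted(records, key=lambda r: r.barcode)
    raise ConfigurationError(f"unknown sort key {key!r}; expected one of {_SORT_KEYS}")


def _fmt_p(log10_p: float | None) -> str:
    """Scientific notation with 4 significant digits, written from log10.

    Formatting from the log10 companion keeps sub-underflow tails (e.g.
    1e-310 and below) printable.
    """
    if log10_p is None:
        return ""
    if log10_p == float("-inf"):
        return "0"
    exponent = math.floor(log10_p)
    mantissa = 10.0 ** (log10_p - exponent)
    if round(mantissa, 3) >= 10.0:  # rounding pushed us into the next decade
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.3f}e{exponent:+03d}"


def write_summary(records: list[IntersectionRecord], path) -> None:
    """Write the summary table as CSV (byte-deterministic for fixed input).

    Columns: Intersections, Degree, Observed.Overlap, Expected.Overlap,
    FE, P.value, adjusted.P.value, log10.P, Elements.  ``log10.P`` is the
    log10 of the adjusted P value; degree-1 rows leave the statistic cells
    empty.
    """
    import csv

    if not records:
        raise ValueError("no records to write")
    with open(path, "wt", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(
            [
                "Intersections",
                "Degree",
                "Observed.Overlap",
                "Expected.Overlap",
                "FE",
                "P.value",
                "adjusted.P.value",
                "log10.P",
                "Elements",
            ]
        )
        for r in records:
            writer.writerow(
                [
                    r.label,
                    r.degree,
                    r.observed,
                    "" if r.expected is None else f"{r.expected:.4g}",
                    "" if r.fe is None else f"{r.fe:.4g}",
                    _fmt_p(r.log10_p_raw),
                    _fmt_p(r.log10_p_adjusted),
                    ""
                    if r.log10_p_adjusted is None
                    else ("-inf" if r.log10_p_adjusted == float("-inf") else f"{r.log10_p_adjusted:.4f}"),
                    "" if r.elements is None else ", ".join(r.elements),
                ]
            )
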