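"""Named element sets over a shared background universe, plus file I/O.

A :class:`SetCollection` holds the sets whose intersections are analyzed
and the background population they were sampled from.  The background may
be given either as a plain size (membership is then trusted) or as an
explicit universe of identifiers (membership is then enforced — a foreign
identifier in a set is almost always a sign that the wrong universe was
supplied, the most common misuse of overlap tests).

Identifier comparison is exact string equality after whitespace trimming;
no case folding (gene-symbol case is meaningful across species).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError, ParseError

__all__ = [
    "SetCollection",
    "read_gmt",
    "read_columns",
    "read_background",
    "write_gmt",
    "count_overlap",
    "exclusive_region_counts",
]

logger = logging.getLogger(__name__)


@dataclass
class SetCollection:
    """Ordered, named element sets with an optional background universe.

    ``background`` is either an integer population size, an explicit
    frozenset of identifiers, or ``None`` (not yet supplied — statistics
    cannot be computed until it is).
    """

    names: list[str]
    members: dict[str, frozenset[str]]
    background: int | frozenset[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ParseError("set names must be unique")
        if set(self.names) != set(self.members):
            raise ConfigurationError("names and members disagree")
        self.members = {name: frozenset(self.members[name]) for name in self.names}
        if self.background is not None:
            self._check_background()

    def _check_background(self) -> None:
        union = frozenset().union(*self.members.values()) if self.members else frozenset()
        if isinstance(self.background, int):
            if self.background < len(union):
                raise ConfigurationError(
                    f"background size {self.background} is smaller than the union "
                    f"of the sets ({len(union)} elements)"
                )
        else:
            self.background = frozenset(self.background)
            foreign = union - self.background
            if foreign:
                sample = ", ".join(sorted(foreign)[:5])
                raise ConfigurationError(
                    f"{len(foreign)} identifiers are absent from the background "
                    f"universe (e.g. {sample}); pass drop_foreign=True to discard them"
                )

    @property
    def t(self) -> int:
        return len(self.names)

    @property
    def background_size(self) -> int:
        if self.background is None:
            raise ConfigurationError("no background population was supplied")
        if isinstance(self.background, int):
            return self.background
        return len(self.background)

    def sizes(self, names: Iterable[str] | None = None) -> tuple[int, ...]:
        picked = list(names) if names is not None else self.names
        return tuple(len(self.members[name]) for name in picked)

    def with_background(
        self, background: int | Iterable[str], drop_foreign: bool = False
    ) -> "SetCollection":
        """Return a copy with the background attached (and validated)."""
        if isinstance(background, int):
            return SetCollection(list(self.names), dict(self.members), background)
        universe = frozenset(str(x).strip() for x in background)
        members = dict(self.members)
        if drop_foreign:
            for name in self.names:
                foreign = members[name] - universe
                if foreign:
                    logger.warning(
                        "set %s: dropping %d identifiers absent from the background",
                        name,
                        len(foreign),
                    )
                    members[name] = members[name] & universe
        return SetCollection(list(self.names), members, universe)


def _clean(token: str) -> str:
    return token.strip()


def read_gmt(path: str | Path) -> SetCollection:
    """Parse a GMT file (set name, description, then members; tab-separated).

    One set per line; duplicate identifiers within a line are removed with
    a logged warning; a line with fewer than three fields or a repeated set
    name is a parse error.  The background is left unset and must be
    supplied separately (:meth:`SetCollection.with_background`).
    """
    names: list[str] = []
    members: dict[str, frozenset[str]] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}, line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, members...), got {len(fields)}"
                )
            name = _clean(fields[0])
            if name in members:
                raise ParseError(f"{path}, line {lineno}: duplicate set name {name!r}")
            elements = [_clean(f) for f in fields[2:] if _clean(f)]
            unique = frozenset(elements)
            if len(unique) < len(elements):
                logger.warning(
                    "%s, line %d: removed %d duplicate identifiers in set %s",
                    path,
                    lineno,
                    len(elements) - len(unique),
                    name,
                )
            names.append(name)
            members[name] = unique
    return SetCollection(names, members)


def read_columns(path: str | Path, delimiter: str | None = None) -> SetCollection:
    """Parse a one-set-per-column table (TSV or CSV, header row = set names).

    Columns may be ragged; empty cells are ignored; cell whitespace is
    trimmed.  An empty header cell is a parse error; an empty column body
    yields an empty set (flagged in the log).
    """
    text = Path(path).read_text(encoding="utf-8")
    if delimiter is None:
        header = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if "\t" in header else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header_cells = [_clean(c) for c in rows[0]]
    if any(not c for c in header_cells):
        raise ParseError(f"{path}: empty header cell (every column needs a set name)")
    columns: list[list[str]] = [[] for _ in header_cells]
    for row in rows[1:]:
        for idx, cell in enumerate(row[: len(header_cells)]):
            token = _clean(cell)
            if token:
                columns[idx].append(token)
    names: list[str] = []
    members: dict[str, frozenset[str]] = {}
    for name, column in zip(header_cells, columns):
        if name in members:
            raise ParseError(f"{path}: duplicate set name {name!r}")
        unique = frozenset(column)
        if len(unique) < len(column):
            logger.warning(
                "%s: removed %d duplicate identifiers in set %s",
                path,
                len(column) - len(unique),
                name,
            )
        if not unique:
            logger.warning("%s: column %s is empty", path, name)
        names.append(name)
        members[name] = unique
    return SetCollection(names, members)


def read_background(path: str | Path) -> frozenset[str]:
    """Read an explicit background universe, one identifier per line."""
    with open(path, "rt", encoding="utf-8") as handle:
        return frozenset(_clean(line) for line in handle if _clean(line))


def write_gmt(collection: SetCollection, path: str | Path) -> None:
    """Write the collection in GMT format (deterministic member order)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        for name in collection.names:
            elements = sorted(collection.members[name])
            handle.write("\t".join([name, "na", *elements]) + "\n")


def count_overlap(collection: SetCollection, combination: Iterable[str]) -> int:
    """Number of elements common to every named set (total, non-exclusive).

    Elements of the intersection may also belong to sets outside the
    combination; this is the quantity the exact test models.
    """
    picked = list(combination)
    if not picked:
        raise ValueError("combination must name at least one set")
    for name in picked:
        if name not in collection.members:
            raise KeyError(f"unknown set name {name!r}")
    inter = collection.members[picked[0]]
    for name in picked[1:]:
        inter = inter & collection.members[name]
    return len(inter)


def intersection_elements(collection: SetCollection, combination: Iterable[str]) -> frozenset[str]:
    """The elements shared by every named set."""
    picked = list(combination)
    inter = collection.members[picked[0]]
    for name in picked[1:]:
        inter = inter & collection.members[name]
    return inter


def exclusive_region_counts(collection: SetCollection) -> dict[str, int]:
    """Venn-style partition of the union into disjoint membership regions.

    Keys are length-``t`` barcodes over {0, 1} (position ``i`` marks
    membership in ``collection.names[i]``); only populated regions appear.
    Counts sum to the size of the union.  Display-only: regions carry no
    P value in this model.
    """
    if collection.t > 20:
        raise ConfigurationError("exclusive regions limited to 20 sets (2^t patterns)")
    union = frozenset().union(*collection.members.values()) if collection.members else frozenset()
    tally: Counter[str] = Counter()
    for element in union:
        barcode = "".join(
            "1" if element in collection.members[name] else "0"
            for name in collection.names
        )
        tally[barcode] += 1
    return dict(tally)
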