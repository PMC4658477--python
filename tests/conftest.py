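import pytest

from exactsets import SetCollection, make_fixture_collection


@pytest.fixture
def abc_collection() -> SetCollection:
    """Three tiny literal sets with hand-countable intersections."""
    return SetCollection(
        names=["A", "B", "C"],
        members={
            "A": frozenset({"a", "b", "c"}),
            "B": frozenset({"b", "c", "d"}),
            "C": frozenset({"c", "d", "e"}),
        },
        background=10,
    )


@pytest.fixture
def planted_collection() -> SetCollection:
    """Synthetic 4-set collection with exactly known overlaps."""
    return make_fixture_collection(
        n=200,
        sizes=[30, 40, 50, 25],
        planted={("A", "B", "C"): 5, ("A", "B"): 12, ("C", "D"): 7},
        seed=11,
    )


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "S1\tfirst set\ta\tb\tc\td\n"
        "S2\tsecond set\tc\td\te\n"
        "S3\tthird set\te\tf\n",
        encoding="utf-8",
    )
    return path
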