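"""Code-space combinatorics: capacity, enumeration, unions, decompositions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpcrmux.codebook import (
    Codebook,
    DecompositionLimitError,
    PartitionLabel,
    TagSignature,
    capacity,
    decompositions,
    enumerate_codebook,
    signature_union,
)

from conftest import random_codebook


@pytest.mark.parametrize(
    "channels,levels,sites,expected",
    [
        (4, 2, 2, 32),
        (5, 2, 2, 50),
        (6, 2, 2, 72),
        (4, 2, 4, 80),
        (6, 2, 6, 728),
        (1, 2, 1, 2),
    ],
)
def test_capacity_known_values(channels, levels, sites, expected):
    assert capacity(channels, levels, sites) == expected


def test_capacity_full_sites_is_ternary_minus_one():
    for c in range(1, 9):
        assert capacity(c, 2, c) == 3**c - 1


def test_capacity_rejects_bad_arguments():
    with pytest.raises(ValueError):
        capacity(4, 2, 5)
    with pytest.raises(ValueError):
        capacity(0, 2, 1)


@pytest.mark.parametrize(
    "channels,sites", [(2, 1), (3, 2), (4, 2), (4, 4), (5, 2)]
)
def test_enumerate_size_matches_capacity(channels, sites):
    cb = enumerate_codebook(channels, 2, sites)
    assert len(cb) == capacity(channels, 2, sites)
    assert len(set(cb.signature_strings)) == len(cb)


def test_enumerate_two_channel_single_site():
    cb = enumerate_codebook(2, 2, 1)
    assert set(cb.signature_strings) == {"10", "20", "01", "02"}


def test_enumerate_contains_named_paper_tags(cb32):
    for sig in ("1100", "2020", "0202"):
        assert sig in cb32.signature_strings


def test_enumerate_is_deterministic():
    a = enumerate_codebook(4, 2, 2)
    b = enumerate_codebook(4, 2, 2)
    assert a.signature_strings == b.signature_strings
    assert list(a.signature_strings) == sorted(a.signature_strings)


def test_signature_rejects_invalid_digits():
    with pytest.raises(ValueError):
        TagSignature.from_string("3000")  # level 3 only from co-presence
    with pytest.raises(ValueError):
        TagSignature.from_string("0000")


def test_codebook_rejects_duplicates_and_overflow():
    t = TagSignature.from_string("10")
    with pytest.raises(ValueError):
        Codebook(2, 2, 1, (t, TagSignature.from_string("10")))
    with pytest.raises(ValueError):
        Codebook(2, 2, 1, (TagSignature.from_string("11"),))  # 2 sites > max 1


def test_union_examples():
    s = TagSignature.from_string
    assert signature_union({s("1000"), s("0100")}).string == "1100"
    assert signature_union({s("1000"), s("2000")}).string == "3000"
    assert signature_union([s("1000"), s("1000")]).string == "1000"


@settings(deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 31), min_size=1, max_size=5))
def test_union_is_commutative_associative_idempotent(indices):
    cb = enumerate_codebook(4, 2, 2)
    members = [cb.tags[i] for i in indices]
    u = signature_union(members)
    assert signature_union(reversed(members)) == u
    assert signature_union(members + members) == u
    # associativity via pairwise folding on the label bitmasks
    acc = members[0].bits
    for m in members[1:]:
        acc = tuple(a | b for a, b in zip(acc, m.bits))
    assert PartitionLabel(acc) == u


def test_decompositions_worked_example(cb3):
    found = decompositions("1100", cb3)
    as_sets = {frozenset(t.string for t in s) for s in found}
    assert as_sets == {
        frozenset({"1100"}),
        frozenset({"1000", "0100"}),
        frozenset({"1100", "1000"}),
        frozenset({"1100", "0100"}),
        frozenset({"1100", "1000", "0100"}),
    }


def test_single_site_label_has_unique_decomposition(cb32):
    for sig in ("1000", "0002"):
        found = decompositions(sig, cb32)
        assert len(found) == 1
        assert {t.string for t in found[0]} == {sig}


def test_level3_label_decomposition(cb32):
    found = decompositions("3000", cb32)
    assert len(found) == 1
    assert {t.string for t in found[0]} == {"1000", "2000"}


def test_decompositions_roundtrip_random_codebooks():
    gen = np.random.default_rng(7)
    for _ in range(20):
        cb = random_codebook(gen, max_channels=3, max_tags=8)
        k = int(gen.integers(1, min(3, len(cb)) + 1))
        subset = [cb.tags[i] for i in gen.choice(len(cb), size=k, replace=False)]
        label = signature_union(subset)
        found = decompositions(label, cb)
        assert frozenset(subset) in found
        for s in found:
            assert signature_union(s) == label


def test_decomposition_limit_guard():
    cb = enumerate_codebook(3, 2, 3)  # 26 tags, label 333 contains all
    with pytest.raises(DecompositionLimitError):
        decompositions("333", cb, max_contained=10)


def test_codebook_json_roundtrip(tmp_path, cb32):
    path = tmp_path / "cb.json"
    cb32.to_json(path)
    back = Codebook.from_json(path)
    assert back == cb32


def test_codebook_csv_reader(tmp_path):
    path = tmp_path / "cb.csv"
    path.write_text("name,signature\nalpha,1100\nbeta,0020\n")
    cb = Codebook.from_csv(path)
    assert cb.by_name("alpha").string == "1100"
    assert cb.channels == 4 and cb.max_sites == 2
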