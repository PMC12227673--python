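"""Combinatorial code space for universal-signal-encoded digital PCR.

A target is identified by a *tag*: a synthetic primer tail carrying one or
more universal hydrolysis-probe binding sites.  Each color channel offers two
probe classes — a low-concentration probe ("1i", intensity level 1) and a
high-concentration probe ("2i", intensity level 2, a 2:1 intensity ratio that
makes signals additive.  A tag's *signature* is therefore a string of digits
over the color channels, each digit in {0, 1, 2}:

    0  no probe site in that channel
    1  site for the 1i probe
    2  site for the 2i probe

e.g. ``"1100"`` = 1i sites in channels 1 and 2 of a four-channel instrument.

When several tags co-occupy one partition their probe consumption combines,
and the partition's observed *label* digit per channel records which probe
classes fired: 0 (none), 1 (only 1i), 2 (only 2i), or 3 (both).  Level 3 can
only arise from co-presence; it never appears in a signature.

Internally a label digit is a bitmask over probe classes (class ``k`` is bit
``k-1``), so for two probe classes the printed digit and the bitmask coincide
(1, 2, 3 = 1|2) and the union of signatures is a per-channel bitwise OR.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TagSignature",
    "PartitionLabel",
    "Codebook",
    "capacity",
    "enumerate_codebook",
    "signature_union",
    "decompositions",
    "DecompositionLimitError",
]


class DecompositionLimitError(RuntimeError):
    """Raised when a label contains too many candidate tags to enumerate."""


def _digits_from_string(s: str) -> tuple[int, ...]:
    if not s or not s.isdigit():
        raise ValueError(f"signature/label string must be non-empty digits, got {s!r}")
    return tuple(int(c) for c in s)


def _digit_bits(digit: int) -> int:
    """Bitmask of probe classes implied by a signature digit (0 -> empty set)."""
    return 0 if digit == 0 else 1 << (digit - 1)


@dataclass(frozen=True, order=True)
class TagSignature:
    """Per-channel probe configuration of one target's tag.

    ``levels`` holds one digit per channel, each in {0, 1, 2}; ``name`` is a
    free-text target identifier defaulting to the digit string itself.
    """

    levels: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        levels = tuple(int(d) for d in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels:
            raise ValueError("signature needs at least one channel")
        if any(d < 0 or d > 2 for d in levels):
            raise ValueError(
                f"signature digits must be in {{0,1,2}} (3 arises only from "
                f"co-presence), got {levels}"
            )
        if all(d == 0 for d in levels):
            raise ValueError("signature must have at least one nonzero digit")
        if not self.name:
            object.__setattr__(self, "name", self.string)

    @classmethod
    def from_string(cls, s: str, name: str = "") -> "TagSignature":
        return cls(_digits_from_string(s), name)

    @property
    def string(self) -> str:
        return "".join(str(d) for d in self.levels)

    @property
    def channels(self) -> int:
        return len(self.levels)

    @property
    def n_sites(self) -> int:
        """Number of probe sites (nonzero digits)."""
        return sum(1 for d in self.levels if d)

    @property
    def bits(self) -> tuple[int, ...]:
        return tuple(_digit_bits(d) for d in self.levels)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.string


@dataclass(frozen=True, order=True)
class PartitionLabel:
    """A partition's observed per-channel amplitude level, digits in {0..3}."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        levels = tuple(int(d) for d in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels:
            raise ValueError("label needs at least one channel")
        if any(d < 0 or d > 3 for d in levels):
            raise ValueError(f"label digits must be in {{0,1,2,3}}, got {levels}")

    @classmethod
    def from_string(cls, s: str) -> "PartitionLabel":
        return cls(_digits_from_string(s))

    @classmethod
    def null(cls, channels: int) -> "PartitionLabel":
        return cls((0,) * channels)

    @property
    def string(self) -> str:
        return "".join(str(d) for d in self.levels)

    @property
    def channels(self) -> int:
        return len(self.levels)

    @property
    def is_null(self) -> bool:
        return all(d == 0 for d in self.levels)

    def contains(self, sig: TagSignature) -> bool:
        """True if every probe class of ``sig`` is present in this label."""
        if sig.channels != self.channels:
            raise ValueError("channel count mismatch")
        return all(
            b == 0 or (b & ld) == b for b, ld in zip(sig.bits, self.levels)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.string


def capacity(channels: int, levels_per_site: int, max_sites: int) -> int:
    """Number of distinct tag signatures encodable on an instrument.

    With ``C`` color channels, ``L`` amplitude levels per probe site and at
    most ``s`` sites per tag the code space holds

        sum_{k=1..s}  C(C, k) * L**k

    signatures (choose the occupied channels, then a level for each).  With
    ``s = C`` this telescopes to ``(L+1)**C - 1``.
    """
    if channels < 1 or levels_per_site < 1 or max_sites < 1:
        raise ValueError("channels, levels_per_site and max_sites must be >= 1")
    if max_sites > channels:
        raise ValueError(
            f"max_sites ({max_sites}) cannot exceed channels ({channels})"
        )
    return sum(
        comb(channels, k) * levels_per_site**k for k in range(1, max_sites + 1)
    )


def _enumerate_signatures(
    channels: int, levels_per_site: int, max_sites: int
) -> Iterator[tuple[int, ...]]:
    for combo in itertools.product(range(levels_per_site + 1), repeat=channels):
        k = sum(1 for d in combo if d)
        if 1 <= k <= max_sites:
            yield combo


@dataclass(frozen=True)
class Codebook:
    """A set of distinct tag signatures sharing one encoding geometry."""

    channels: int
    levels_per_site: int
    max_sites: int
    tags: tuple[TagSignature, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags", tuple(self.tags))
        if self.channels < 1 or self.levels_per_site < 1 or self.max_sites < 1:
            raise ValueError("channels, levels_per_site, max_sites must be >= 1")
        if self.max_sites > self.channels:
            raise ValueError("max_sites cannot exceed channels")
        seen: set[tuple[int, ...]] = set()
        names: set[str] = set()
        for t in self.tags:
            if t.channels != self.channels:
                raise ValueError(f"tag {t.string} has wrong channel count")
            if t.n_sites > self.max_sites:
                raise ValueError(f"tag {t.string} exceeds max_sites={self.max_sites}")
            if any(d > self.levels_per_site for d in t.levels):
                raise ValueError(
                    f"tag {t.string} exceeds levels_per_site={self.levels_per_site}"
                )
            if t.levels in seen:
                raise ValueError(f"duplicate signature {t.string}")
            if t.name in names:
                raise ValueError(f"duplicate tag name {t.name!r}")
            seen.add(t.levels)
            names.add(t.name)
        cap = capacity(self.channels, self.levels_per_site, self.max_sites)
        if len(self.tags) > cap:
            raise ValueError(f"codebook size {len(self.tags)} exceeds capacity {cap}")

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self) -> Iterator[TagSignature]:
        return iter(self.tags)

    @property
    def signature_strings(self) -> tuple[str, ...]:
        return tuple(t.string for t in self.tags)

    def by_signature(self, s: str | TagSignature) -> TagSignature:
        key = s.string if isinstance(s, TagSignature) else s
        for t in self.tags:
            if t.string == key:
                return t
        raise KeyError(f"no tag with signature {key!r}")

    def by_name(self, name: str) -> TagSignature:
        for t in self.tags:
            if t.name == name:
                return t
        raise KeyError(f"no tag named {name!r}")

    # --- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "channels": self.channels,
            "levels_per_site": self.levels_per_site,
            "max_sites": self.max_sites,
            "tags": [{"name": t.name, "signature": t.string} for t in self.tags],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        try:
            tags = tuple(
                TagSignature.from_string(t["signature"], t.get("name", ""))
                for t in d["tags"]
            )
            return cls(
                int(d["channels"]),
                int(d["levels_per_site"]),
                int(d["max_sites"]),
                tags,
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed codebook definition: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        levels_per_site: int = 2,
        max_sites: int | None = None,
    ) -> "Codebook":
        """Read a two-column (name, signature) CSV; geometry inferred."""
        import pandas as pd

        df = pd.read_csv(path, dtype=str)
        cols = [c.strip().lower() for c in df.columns]
        if "signature" not in cols or "name" not in cols:
            raise ValueError("codebook CSV needs 'name' and 'signature' columns")
        df.columns = cols
        tags = tuple(
            TagSignature.from_string(str(r.signature).strip(), str(r.name).strip())
            for r in df.itertuples()
        )
        channels = tags[0].channels
        sites = max_sites if max_sites is not None else max(t.n_sites for t in tags)
        return cls(channels, levels_per_site, sites, tags)


def enumerate_codebook(
    channels: int, levels_per_site: int = 2, max_sites: int = 2
) -> Codebook:
    """Canonical full codebook: every admissible signature, lexicographic order.

    The size always equals :func:`capacity`.  Tag names default to the digit
    strings; user codebooks may assign any bijection of targets to signatures.
    """
    sigs = sorted(_enumerate_signatures(channels, levels_per_site, max_sites))
    tags = tuple(TagSignature(s) for s in sigs)
    return Codebook(channels, levels_per_site, max_sites, tags)


def signature_union(members: Iterable[TagSignature]) -> PartitionLabel:
    """Label generated when all ``members`` co-occupy one partition.

    Per channel the label digit encodes the set of probe classes consumed
    across members ({} -> 0, {1i} -> 1, {2i} -> 2, {1i, 2i} -> 3); probe
    consumption saturates, so the operation is an idempotent, commutative,
    associative bitwise OR.
    """
    members = list(members)
    if not members:
        raise ValueError("signature_union needs a non-empty set of tags")
    channels = members[0].channels
    acc = [0] * channels
    for m in members:
        if m.channels != channels:
            raise ValueError("all members must share the channel count")
        for c, b in enumerate(m.bits):
            acc[c] |= b
    return PartitionLabel(tuple(acc))


def decompositions(
    label: PartitionLabel | str,
    codebook: Codebook,
    max_contained: int = 20,
) -> list[frozenset[TagSignature]]:
    """All tag subsets of ``codebook`` whose co-presence reproduces ``label``.

    A partition labelled e.g. ``1100`` is ambiguous between the 1100 tag alone
    and any combination of contained tags whose union is 1100.  Enumeration is
    exponential in the number of contained tags; ``max_contained`` guards
    pathological codebooks.
    """
    if isinstance(label, str):
        label = PartitionLabel.from_string(label)
    contained = [t for t in codebook.tags if label.contains(t)]
    if len(contained) > max_contained:
        raise DecompositionLimitError(
            f"label {label.string} contains {len(contained)} candidate tags "
            f"(limit {max_contained})"
        )
    out: list[frozenset[TagSignature]] = []
    for r in range(1, len(contained) + 1):
        for subset in itertools.combinations(contained, r):
            if signature_union(subset) == label:
                out.append(frozenset(subset))
    return out
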