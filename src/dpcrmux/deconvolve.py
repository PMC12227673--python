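"""Hierarchical Poisson deconvolution of partition labels into copy numbers.

A partition label can be ambiguous: label 1100 may come from the 1100 tag
alone or from tags 1000 + 0100 co-occupying a partition.  Under Poisson
loading, tag presence is independent across tags with per-partition occupancy
probability ``1 - exp(-lambda_t)``, which lets the ambiguity be resolved
hierarchically from simple tags to composite ones:

1.  P_0 partitions carry the all-zero label; for a single-channel tag,
    ``lambda = ln(1 + P_L / P_0)``.
2.  For a tag whose signature L spans more channels, first compute the
    *expected counts* E_L — partitions that would show label L from
    combinations of already-estimated contained tags alone:

        E_L = P_0 * sum over subsets S of contained tags with union(S) = L
                    of prod_{t in S} (exp(lambda_t) - 1)

    (for label 1100 with contained tags 1000 and 0100 this is the familiar
    ``P_0 * [P_1000/P_0] * [P_0100/P_0]``).
3.  The corrected count ``P'_L = P_L - E_L`` (clamped at 0) still includes
    partitions where the L tag co-occurs with contained tags; multiplying by
    ``exp(-lambda_t)`` for each contained tag t gives ``P*_L``, the expected
    number of partitions holding the L tag alone, whence
    ``lambda_L = ln(1 + P*_L / P_0)`` and copies = N * lambda.

Processing tags in ascending order of probe-site count makes every required
lambda available when needed; applied to exact expected counts the scheme
recovers the generating lambdas identically (the subsets containing the tag
itself telescope to ``P_0 * (e^lambda - 1) * prod e^{lambda_t}``).

Labels matching no signature — including any label with a level-3 digit —
carry real information about co-presence but are not consumed by the scheme;
they are excluded from estimation and reported with their counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import Codebook, PartitionLabel, TagSignature
from .signal import LabelCounts

__all__ = [
    "SaturatedReactionError",
    "TagEstimate",
    "DecodeResult",
    "DeconvolutionPlan",
    "estimate_single_channel",
    "estimate_all",
    "label_probabilities",
]

MAX_CHANNELS_ENUMERATED = 10  # label lattice has 4**C states


class SaturatedReactionError(RuntimeError):
    """No null partitions: the reaction is too concentrated to quantify."""


@dataclass(frozen=True)
class TagEstimate:
    """Per-tag deconvolution output with all intermediate quantities."""

    name: str
    signature: str
    n_sites: int
    count: int              # P_L, exact-label partition count
    expected: float         # E_L, co-presence expectation from contained tags
    corrected: float        # P'_L = max(P_L - E_L, 0)
    corrected_final: float  # P*_L = P'_L * prod exp(-lambda_t)
    lam: float              # mean copies per partition
    copies: float           # N * lambda


@dataclass(frozen=True)
class DecodeResult:
    """Full deconvolution result for one well."""

    estimates: tuple[TagEstimate, ...]
    n_partitions: int
    n_null: int
    excluded: Mapping[str, int]  # non-signature labels (e.g. level-3) + counts

    @property
    def lambdas(self) -> dict[str, float]:
        return {e.name: e.lam for e in self.estimates}

    @property
    def copies(self) -> dict[str, float]:
        return {e.name: e.copies for e in self.estimates}

    @property
    def total_copies(self) -> float:
        return float(sum(e.copies for e in self.estimates))

    @property
    def n_excluded(self) -> int:
        return int(sum(self.excluded.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tag": e.name,
                    "signature": e.signature,
                    "sites": e.n_sites,
                    "count": e.count,
                    "expected": e.expected,
                    "corrected": e.corrected,
                    "corrected_final": e.corrected_final,
                    "lambda": e.lam,
                    "copies": e.copies,
                }
                for e in self.estimates
            ]
        )


def estimate_single_channel(counts: LabelCounts, tag: TagSignature) -> float:
    """Occupancy of a single-site tag: ``lambda = ln(1 + P_L / P_0)``.

    Partitions showing a single-site tag's signature exactly are known to
    contain that target and no others, so the classic dPCR ratio applies
    directly.  With a one-tag codebook P_0 = N - P_pos and this reduces to
    the textbook ``-ln(1 - P_pos / N)``.
    """
    if tag.n_sites != 1:
        raise ValueError("estimate_single_channel requires a single-site tag")
    p0 = counts.n_null
    if p0 == 0:
        raise SaturatedReactionError(
            "no null partitions; dilute the sample and repeat"
        )
    return math.log1p(counts.get(tag.string) / p0)


class DeconvolutionPlan:
    """Precomputed estimation schedule for one codebook.

    Building the contained-tag sets and their label-reproducing subsets once
    lets :meth:`lambdas_from_codes` run in microseconds per well, which the
    Monte Carlo design studies rely on.
    """

    def __init__(self, codebook: Codebook, max_contained: int = 20) -> None:
        if codebook.channels > MAX_CHANNELS_ENUMERATED:
            raise ValueError(
                f"deconvolution supports at most {MAX_CHANNELS_ENUMERATED} channels"
            )
        sigs = set(codebook.signature_strings)
        if len(sigs) != len(codebook):
            raise ValueError("codebook signatures must be distinct")
        self.codebook = codebook
        self.n_labels = 4**codebook.channels
        weights = 4 ** np.arange(codebook.channels - 1, -1, -1)
        self.sig_codes = np.array(
            [np.dot(t.levels, weights) for t in codebook.tags], dtype=np.int64
        )
        # process ascending by site count, lexicographic within an order;
        # same-order distinct tags are never contained in each other, so the
        # result is order-independent within an order
        self.order = sorted(
            range(len(codebook)),
            key=lambda i: (codebook.tags[i].n_sites, codebook.tags[i].levels),
        )
        self.contained: list[list[int]] = []
        self.subsets: list[list[tuple[int, ...]]] = []
        for i, tag in enumerate(codebook.tags):
            label = PartitionLabel(tag.levels)
            inside = [
                j
                for j, other in enumerate(codebook.tags)
                if j != i and label.contains(other)
            ]
            if len(inside) > max_contained:
                raise ValueError(
                    f"tag {tag.string} contains {len(inside)} other tags "
                    f"(limit {max_contained})"
                )
            subs: list[tuple[int, ...]] = []
            target = int(self.sig_codes[i])
            for r in range(1, len(inside) + 1):
                for S in itertools.combinations(inside, r):
                    u = 0
                    for j in S:
                        u |= int(self.sig_codes[j])
                    if u == target:
                        subs.append(S)
            self.contained.append(inside)
            self.subsets.append(subs)

    def lambdas_from_codes(self, count_vector: np.ndarray) -> np.ndarray:
        """Per-tag lambda (codebook order) from a 4**C label count vector."""
        p0 = float(count_vector[0])
        if p0 == 0:
            raise SaturatedReactionError(
                "no null partitions; dilute the sample and repeat"
            )
        lam = np.zeros(len(self.codebook))
        ratio = np.zeros(len(self.codebook))  # exp(lambda) - 1 per tag
        for i in self.order:
            p_l = float(count_vector[self.sig_codes[i]])
            e_l = p0 * sum(
                math.prod(ratio[j] for j in S) for S in self.subsets[i]
            )
            p_prime = max(p_l - e_l, 0.0)
            p_star = p_prime * math.exp(-sum(lam[j] for j in self.contained[i]))
            lam[i] = math.log1p(p_star / p0)
            ratio[i] = math.expm1(lam[i])
        return lam

    def counts_to_vector(self, counts: LabelCounts) -> np.ndarray:
        vec = np.zeros(self.n_labels)
        weights = 4 ** np.arange(self.codebook.channels - 1, -1, -1)
        for label, n in counts.counts.items():
            code = int(np.dot([int(c) for c in label], weights))
            vec[code] += n
        return vec


def estimate_all(counts: LabelCounts, codebook: Codebook) -> DecodeResult:
    """Deconvolve label counts into per-tag occupancies and copy numbers."""
    if counts.channels != codebook.channels:
        raise ValueError(
            f"counts are {counts.channels}-channel, codebook is "
            f"{codebook.channels}-channel"
        )
    plan = DeconvolutionPlan(codebook)
    vec = plan.counts_to_vector(counts)
    p0 = counts.n_null
    if p0 == 0:
        raise SaturatedReactionError(
            "no null partitions; dilute the sample and repeat"
        )
    lam = plan.lambdas_from_codes(vec)
    n = counts.n_total
    estimates = []
    ratio = np.expm1(lam)
    for i, tag in enumerate(codebook.tags):
        p_l = counts.get(tag.string)
        e_l = p0 * sum(
            math.prod(ratio[j] for j in S) for S in plan.subsets[i]
        )
        p_prime = max(p_l - e_l, 0.0)
        p_star = p_prime * math.exp(-sum(lam[j] for j in plan.contained[i]))
        estimates.append(
            TagEstimate(
                name=tag.name,
                signature=tag.string,
                n_sites=tag.n_sites,
                count=p_l,
                expected=float(e_l),
                corrected=float(p_prime),
                corrected_final=float(p_star),
                lam=float(lam[i]),
                copies=float(n * lam[i]),
            )
        )
    signature_set = set(codebook.signature_strings)
    excluded = {
        label: cnt
        for label, cnt in counts.counts.items()
        if label not in signature_set and label != counts.null_label
    }
    return DecodeResult(
        estimates=tuple(estimates),
        n_partitions=n,
        n_null=p0,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# exact label distribution (oracle and study engine)
# ---------------------------------------------------------------------------

def label_probability_vector(
    codebook: Codebook, lambdas: Sequence[float] | Mapping[str, float]
) -> np.ndarray:
    """Exact label probabilities over all 4**C codes under independent
    Poisson presence.

    Dynamic program over the label lattice: tags are folded in one at a time,
    each present with probability ``1 - exp(-lambda)``; the union of present
    signatures is a bitwise OR of the 2-bit-per-channel codes.
    """
    c = codebook.channels
    if c > MAX_CHANNELS_ENUMERATED:
        raise ValueError(
            f"label enumeration supports at most {MAX_CHANNELS_ENUMERATED} channels"
        )
    if isinstance(lambdas, Mapping):
        lam = np.array([float(lambdas.get(t.name, 0.0)) for t in codebook.tags])
    else:
        lam = np.asarray(lambdas, dtype=float)
        if lam.shape != (len(codebook),):
            raise ValueError("need one lambda per codebook tag")
    if np.any(lam < 0):
        raise ValueError("lambdas must be >= 0")
    weights = 4 ** np.arange(c - 1, -1, -1)
    codes = np.arange(4**c)
    probs = np.zeros(4**c)
    probs[0] = 1.0
    p_present = -np.expm1(-lam)
    for tag, p in zip(codebook.tags, p_present):
        if p == 0.0:
            continue
        s = int(np.dot(tag.levels, weights))
        moved = probs * p
        probs = probs * (1.0 - p)
        np.add.at(probs, codes | s, moved)
    return probs


def label_probabilities(
    codebook: Codebook, lambdas: Sequence[float] | Mapping[str, float]
) -> dict[str, float]:
    """Exact achievable-label probabilities as a {label string: p} map."""
    probs = label_probability_vector(codebook, lambdas)
    c = codebook.channels
    shifts = 2 * np.arange(c - 1, -1, -1)
    out: dict[str, float] = {}
    for code in np.nonzero(probs)[0]:
        digits = (int(code) >> shifts) & 3
        out["".join(map(str, digits))] = float(probs[code])
    return out
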