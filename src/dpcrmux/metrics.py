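"""Evaluation metrics: partition/target accuracy, VAF, replicate comparison."""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .deconvolve import DecodeResult

__all__ = [
    "ConfusionSummary",
    "PartitionAccuracy",
    "VAFResult",
    "partition_accuracy",
    "target_calls_confusion",
    "vaf",
    "compare_to_background",
]


def _fraction_str(num: int, den: int) -> str:
    pct = 100.0 * num / den if den else float("nan")
    return f"{num}/{den} ({pct:.1f}%)"


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts with the ratios reported as exact fractions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def as_fractions(self) -> dict[str, str]:
        """Printable forms, e.g. accuracy '81/96 (84.4%)'."""
        return {
            "accuracy": _fraction_str(self.tp + self.tn, self.total),
            "sensitivity": _fraction_str(self.tp, self.tp + self.fn),
            "specificity": _fraction_str(self.tn, self.tn + self.fp),
        }

    def accuracy_fraction(self) -> Fraction:
        return Fraction(self.tp + self.tn, self.total)


@dataclass(frozen=True)
class PartitionAccuracy:
    """Positive-partition accuracy with both denominator conventions.

    ``n_assigned`` counts partitions whose label matched some codebook
    signature; ``n_unassigned`` counts positive partitions with a
    non-signature label (e.g. level-3 co-presence labels).  ``accuracy`` uses
    the assigned denominator; ``accuracy_all_positive`` folds the unassigned
    partitions into the denominator.
    """

    n_expected: int
    n_assigned: int
    n_unassigned: int

    @property
    def n_positive(self) -> int:
        return self.n_assigned + self.n_unassigned

    @property
    def accuracy(self) -> float:
        return self.n_expected / self.n_assigned

    @property
    def accuracy_all_positive(self) -> float:
        return self.n_expected / self.n_positive


def partition_accuracy(
    assignments: Sequence[str | None],
    truth_set: set[str],
    n_unassigned: int = 0,
) -> PartitionAccuracy:
    """Fraction of positive partitions assigned to a tag expected in the sample.

    ``assignments`` holds one entry per signature-matching partition (tag
    name) or ``None`` for null partitions; ``n_unassigned`` counts additional
    positive partitions whose label matched no signature.
    """
    assigned = [a for a in assignments if a is not None]
    if not assigned and n_unassigned == 0:
        raise ValueError("no positive partitions; accuracy is undefined")
    expected = sum(1 for a in assigned if a in truth_set)
    return PartitionAccuracy(expected, len(assigned), n_unassigned)


def target_calls_confusion(
    calls: Mapping[str, bool], truth: Mapping[str, bool]
) -> ConfusionSummary:
    """Standard confusion counts over a shared target universe."""
    if set(calls) != set(truth):
        raise ValueError("calls and truth must cover the same target universe")
    tp = fp = tn = fn = 0
    for target, called in calls.items():
        present = truth[target]
        if called and present:
            tp += 1
        elif called and not present:
            fp += 1
        elif not called and present:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp, fp, tn, fn)


@dataclass(frozen=True)
class VAFResult:
    """Variant allele fractions relative to a reference amplicon."""

    vaf: Mapping[str, float]
    reference_tag: str

    @property
    def mean_vaf(self) -> float:
        if not self.vaf:
            return 0.0
        return float(np.mean(list(self.vaf.values())))


def vaf(result: DecodeResult, reference_tag: str) -> VAFResult:
    """Per-variant VAF = variant copies / reference copies; mean across panel.

    The reference tag targets a locus present in every genome at known copy,
    anchoring the denominator; mean VAF across targets is the usual summary
    of tumor burden in liquid-biopsy panels.
    """
    copies = result.copies
    if reference_tag not in copies:
        raise KeyError(f"reference tag {reference_tag!r} not in decode result")
    ref = copies[reference_tag]
    if ref <= 0:
        raise ValueError("reference copies must be > 0 for a defined VAF")
    out = {
        name: c / ref for name, c in copies.items() if name != reference_tag
    }
    return VAFResult(out, reference_tag)


def compare_to_background(
    replicate_values_a: Sequence[float],
    replicate_values_b: Sequence[float],
    method: str = "auto",
) -> float:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) p-value between replicate
    groups, e.g. a sample's per-replicate counts versus background."""
    a = np.asarray(replicate_values_a, dtype=float)
    b = np.asarray(replicate_values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicate values per group")
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
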