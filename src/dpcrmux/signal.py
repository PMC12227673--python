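"""Amplitude preprocessing, partition classification and QC.

Pipeline for one well of per-partition fluorescence data:

1. :func:`subtract_baseline` — per channel, subtract the 3rd percentile so the
   no-target cluster sits near 0.
2. :func:`compensate_crosstalk` — multiply each partition vector by the
   inverse of the spectral crosstalk matrix.
3. :func:`calibrate` — divide each channel by its 1i cluster center so the
   low-intensity reference sits at 1.0 (the 2i cluster then sits near 2).
4. :func:`classify_partitions` — threshold each channel into levels 0/1/2/3
   and concatenate into a partition label.
5. :func:`call_tags` / :func:`euclidean_qc` — presence calls and per-partition
   distance-to-ideal QC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import Codebook, PartitionLabel, TagSignature

__all__ = [
    "AmplitudeMatrix",
    "ThresholdSet",
    "LabelCounts",
    "CrosstalkMatrix",
    "subtract_baseline",
    "compensate_crosstalk",
    "calibrate",
    "classify_partitions",
    "classification_codes",
    "call_tags",
    "euclidean_qc",
]

BASELINE_PERCENTILE = 3.0
DEFAULT_THRESHOLDS = (0.5, 1.5, 2.5)


def _channel_names(c: int) -> tuple[str, ...]:
    return tuple(f"ch{i + 1}" for i in range(c))


@dataclass(frozen=True)
class AmplitudeMatrix:
    """N partitions x C channels of continuous fluorescence values."""

    values: np.ndarray
    channels: tuple[str, ...] = ()
    well: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("amplitude matrix must be 2-D (partitions x channels)")
        if v.shape[0] < 1:
            raise ValueError("amplitude matrix must contain at least one partition")
        if not np.all(np.isfinite(v)):
            raise ValueError("amplitude matrix contains non-finite values")
        object.__setattr__(self, "values", v)
        chans = tuple(self.channels) or _channel_names(v.shape[1])
        if len(chans) != v.shape[1]:
            raise ValueError("channel-name count does not match matrix width")
        object.__setattr__(self, "channels", chans)

    @property
    def n_partitions(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def replace(self, values: np.ndarray) -> "AmplitudeMatrix":
        return AmplitudeMatrix(values, self.channels, self.well)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.channels))
        df.insert(0, "well", self.well if self.well is not None else "A1")
        df.insert(0, "partition_id", np.arange(self.n_partitions))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AmplitudeMatrix":
        chan_cols = [c for c in df.columns if c not in ("partition_id", "well")]
        if not chan_cols:
            raise ValueError("no channel columns found")
        well = None
        if "well" in df.columns and df["well"].nunique() == 1:
            well = str(df["well"].iloc[0])
        return cls(df[chan_cols].to_numpy(dtype=float), tuple(chan_cols), well)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel ascending cuts (t1 < t2 < t3) separating levels 0/1/2/3."""

    cuts: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        cuts = tuple(tuple(float(x) for x in c) for c in self.cuts)
        for c in cuts:
            if len(c) != 3 or not (c[0] < c[1] < c[2]):
                raise ValueError(f"thresholds must be 3 strictly ascending cuts, got {c}")
        object.__setattr__(self, "cuts", cuts)

    @classmethod
    def uniform(
        cls, channels: int, cuts: Sequence[float] = DEFAULT_THRESHOLDS
    ) -> "ThresholdSet":
        return cls(tuple(tuple(cuts) for _ in range(channels)))

    @property
    def n_channels(self) -> int:
        return len(self.cuts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.cuts, dtype=float)


@dataclass(frozen=True)
class CrosstalkMatrix:
    """C x C spectral mixing: entry (i, j) is the fraction of channel-j true
    signal appearing in channel i; the diagonal is 1 by convention."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("crosstalk matrix must be square")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("crosstalk matrix diagonal must equal 1")
        if np.any(m < 0):
            raise ValueError("crosstalk coefficients must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def identity(cls, channels: int) -> "CrosstalkMatrix":
        return cls(np.eye(channels))

    @classmethod
    def uniform_bleed(cls, channels: int, alpha: float) -> "CrosstalkMatrix":
        """Every channel receives fraction ``alpha`` of every other channel."""
        m = np.full((channels, channels), float(alpha))
        np.fill_diagonal(m, 1.0)
        return cls(m)

    @classmethod
    def adjacent_bleed(cls, channels: int, alpha: float) -> "CrosstalkMatrix":
        """Each channel leaks fraction ``alpha`` into its next spectral
        neighbor (the classic red-shifted dye bleed-through pattern)."""
        m = np.eye(channels)
        for c in range(channels - 1):
            m[c + 1, c] = float(alpha)
        return cls(m)

    def mix(self, values: np.ndarray) -> np.ndarray:
        """Apply mixing to row vectors of true signal."""
        return values @ self.matrix.T

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix).to_csv(path, index=False, header=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrosstalkMatrix":
        return cls(pd.read_csv(path, header=None).to_numpy(dtype=float))


@dataclass(frozen=True)
class LabelCounts:
    """Tally of partitions per label for one well (the P_L quantities)."""

    counts: Mapping[str, int]
    channels: int
    n_total: int = 0

    def __post_init__(self) -> None:
        counts = {str(k): int(v) for k, v in self.counts.items() if v}
        for k in counts:
            PartitionLabel.from_string(k)  # validates digits
            if len(k) != self.channels:
                raise ValueError(f"label {k!r} does not have {self.channels} digits")
        total = sum(counts.values())
        n = self.n_total or total
        if n != total:
            raise ValueError(f"counts sum to {total}, expected n_total={n}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n_total", n)

    @property
    def null_label(self) -> str:
        return "0" * self.channels

    @property
    def n_null(self) -> int:
        """P_0: partitions with no amplified target."""
        return self.counts.get(self.null_label, 0)

    def get(self, label: str | PartitionLabel) -> int:
        key = label.string if isinstance(label, PartitionLabel) else label
        return self.counts.get(key, 0)

    @classmethod
    def from_labels(cls, labels: Sequence[str], channels: int | None = None) -> "LabelCounts":
        if not labels:
            raise ValueError("empty label sequence")
        c = channels if channels is not None else len(labels[0])
        return cls(Counter(labels), c)

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.counts), name="partitions").sort_index()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def subtract_baseline(
    matrix: AmplitudeMatrix, percentile: float = BASELINE_PERCENTILE
) -> AmplitudeMatrix:
    """Subtract the per-channel 3rd percentile from every partition.

    Corrects well-to-well baseline drift so the no-target cluster sits near 0
    in every channel.  Percentiles use linear interpolation between order
    statistics.  Negative values are retained, not clipped.
    """
    base = np.percentile(matrix.values, percentile, axis=0)
    return matrix.replace(matrix.values - base)


def compensate_crosstalk(
    matrix: AmplitudeMatrix, xt: CrosstalkMatrix
) -> AmplitudeMatrix:
    """Remove spectral mixing by multiplying each vector by the inverse matrix."""
    if xt.n_channels != matrix.n_channels:
        raise ValueError(
            f"crosstalk matrix is {xt.n_channels}-channel, data is "
            f"{matrix.n_channels}-channel"
        )
    try:
        corrected = np.linalg.solve(xt.matrix, matrix.values.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "crosstalk matrix is singular and cannot be inverted; check the "
            "single-color control reactions it was derived from"
        ) from exc
    return matrix.replace(corrected)


def calibrate(
    matrix: AmplitudeMatrix, reference: Sequence[float]
) -> AmplitudeMatrix:
    """Scale each channel so its 1i cluster center sits at intensity 1.0."""
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (matrix.n_channels,):
        raise ValueError("need one reference center per channel")
    if np.any(ref <= 0):
        raise ValueError("reference centers must be positive")
    return matrix.replace(matrix.values / ref)


def estimate_reference_centers(
    matrix: AmplitudeMatrix,
    thresholds: ThresholdSet | None = None,
) -> np.ndarray:
    """Provisional 1i cluster centers: per channel, the median of values that
    classify as level 1 in a first thresholding pass on the raw scale."""
    thr = thresholds or ThresholdSet.uniform(matrix.n_channels)
    cuts = thr.as_array()
    centers = np.ones(matrix.n_channels)
    for c in range(matrix.n_channels):
        col = matrix.values[:, c]
        sel = (col >= cuts[c, 0]) & (col < cuts[c, 1])
        if sel.any():
            centers[c] = np.median(col[sel])
    return centers


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _digits_matrix(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Per-channel level digits (0..3) via threshold comparison."""
    # value < t1 -> 0, < t2 -> 1, < t3 -> 2, else 3
    return (values[:, :, None] >= cuts[None, :, :]).sum(axis=2)


def classification_codes(
    matrix: AmplitudeMatrix, thresholds: ThresholdSet | None = None
) -> np.ndarray:
    """Integer label codes (2 bits per channel, channel 1 most significant)."""
    thr = thresholds or ThresholdSet.uniform(matrix.n_channels)
    if thr.n_channels != matrix.n_channels:
        raise ValueError("threshold channel count does not match data")
    digits = _digits_matrix(matrix.values, thr.as_array())
    weights = 4 ** np.arange(matrix.n_channels - 1, -1, -1)
    return digits @ weights


def codes_to_strings(codes: np.ndarray, channels: int) -> list[str]:
    digits = (codes[:, None] >> (2 * np.arange(channels - 1, -1, -1))) & 3
    return ["".join(map(str, row)) for row in digits]


def classify_partitions(
    matrix: AmplitudeMatrix, thresholds: ThresholdSet | None = None
) -> tuple[list[PartitionLabel], LabelCounts]:
    """Assign every partition a label by per-channel amplitude thresholding."""
    codes = classification_codes(matrix, thresholds)
    strings = codes_to_strings(codes, matrix.n_channels)
    labels = [PartitionLabel.from_string(s) for s in strings]
    return labels, LabelCounts.from_labels(strings, matrix.n_channels)


def call_tags(
    counts: LabelCounts, codebook: Codebook, min_partitions: int = 1
) -> set[str]:
    """Tags called present: >= ``min_partitions`` partitions whose label
    matches the tag's expected optical signature exactly."""
    if min_partitions < 1:
        raise ValueError("min_partitions must be >= 1")
    return {
        t.name for t in codebook.tags if counts.get(t.string) >= min_partitions
    }


def euclidean_qc(
    matrix: AmplitudeMatrix,
    assignments: Sequence[str | TagSignature],
    codebook: Codebook,
) -> np.ndarray:
    """Distance of each partition's signal to its assigned tag's ideal vector.

    Channels where the assigned signature has no probe site are zeroed first
    (suppressing baseline noise in undetected channels), then the Euclidean
    distance to the signature digits, read as intensities, is returned.
    """
    if len(assignments) != matrix.n_partitions:
        raise ValueError("need one assignment per partition")
    dist = np.empty(matrix.n_partitions)
    for i, a in enumerate(assignments):
        if isinstance(a, TagSignature):
            sig = a
        else:
            try:
                sig = codebook.by_signature(a)
            except KeyError:
                try:
                    sig = codebook.by_name(a)
                except KeyError:
                    raise ValueError(f"assignment {a!r} is not in the codebook")
        ideal = np.asarray(sig.levels, dtype=float)
        masked = np.where(ideal == 0, 0.0, matrix.values[i])
        dist[i] = np.linalg.norm(masked - ideal)
    return dist
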