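"""End-to-end decode pipeline: preprocess -> classify -> quantify."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codebook import Codebook
from .deconvolve import DecodeResult, estimate_all
from .signal import (
    AmplitudeMatrix,
    CrosstalkMatrix,
    LabelCounts,
    ThresholdSet,
    calibrate,
    classify_partitions,
    compensate_crosstalk,
    estimate_reference_centers,
    subtract_baseline,
)

__all__ = ["DecodePipelineResult", "preprocess", "decode_well"]


@dataclass(frozen=True)
class DecodePipelineResult:
    corrected: AmplitudeMatrix
    counts: LabelCounts
    result: DecodeResult


def preprocess(
    matrix: AmplitudeMatrix,
    crosstalk: CrosstalkMatrix | None = None,
    reference: np.ndarray | None = None,
    thresholds: ThresholdSet | None = None,
) -> AmplitudeMatrix:
    """Baseline-subtract, compensate crosstalk and calibrate one well.

    When no explicit 1i reference centers are given they are estimated from a
    provisional thresholding pass on the corrected data.
    """
    m = subtract_baseline(matrix)
    if crosstalk is not None:
        m = compensate_crosstalk(m, crosstalk)
    if reference is None:
        reference = estimate_reference_centers(m, thresholds)
    return calibrate(m, reference)


def decode_well(
    matrix: AmplitudeMatrix,
    codebook: Codebook,
    crosstalk: CrosstalkMatrix | None = None,
    thresholds: ThresholdSet | None = None,
    skip_preprocess: bool = False,
) -> DecodePipelineResult:
    """Full pipeline on one well's raw amplitudes."""
    if matrix.n_channels != codebook.channels:
        raise ValueError(
            f"data has {matrix.n_channels} channels, codebook has "
            f"{codebook.channels}"
        )
    corrected = (
        matrix if skip_preprocess else preprocess(matrix, crosstalk, None, thresholds)
    )
    _, counts = classify_partitions(corrected, thresholds)
    result = estimate_all(counts, codebook)
    return DecodePipelineResult(corrected, counts, result)
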