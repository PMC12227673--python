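"""Synthetic per-partition fluorescence data with known ground truth.

Molecules of each target are loaded into partitions by Poisson statistics:
with ``copies`` expected molecules spread uniformly and independently over
``N`` partitions, per-partition molecule counts are iid Poisson(copies/N), so
each partition holds >= 1 molecule of a tag independently with probability
``1 - exp(-copies/N)``.  The simulator samples occupancy directly from that
Bernoulli representation (exact at the occupancy level by Poisson thinning).

Observed fluorescence per partition is built from the union of the occupying
tags' signatures: per channel the consumed probe classes give a level in
{0,1,2,3} with default calibrated intensities 0/1/2/3 (level 3 = 1i + 2i,
additive by the 2:1 probe concentration design).  Configurable instrument
artifacts: Gaussian cluster scatter, additive baseline offsets, "rain"
(partitions smeared below their cluster), incomplete hydrolysis (a 2i
contribution attenuated, e.g. a [0,0,1,2] tag rendering at [0,0,1,1.5]), and
linear spectral crosstalk.  Values are not clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .codebook import Codebook, signature_union
from .signal import AmplitudeMatrix, CrosstalkMatrix

__all__ = [
    "TruthSpec",
    "NoiseModel",
    "SimulatedRun",
    "load_partitions",
    "true_label_codes",
    "render_signal",
    "simulate_run",
]

DEFAULT_PARTITIONS = 26_000


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one simulated well."""

    codebook: Codebook
    copies: Mapping[str, float]  # tag name -> expected copies in the reaction
    partitions: int = DEFAULT_PARTITIONS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.partitions < 1:
            raise ValueError("partitions must be >= 1")
        copies = {str(k): float(v) for k, v in self.copies.items()}
        for name, c in copies.items():
            self.codebook.by_name(name)  # KeyError on unknown tag
            if c < 0:
                raise ValueError(f"copies for {name!r} must be >= 0")
        object.__setattr__(self, "copies", copies)

    def copies_vector(self) -> np.ndarray:
        """Expected copies per codebook tag, codebook order."""
        return np.array(
            [self.copies.get(t.name, 0.0) for t in self.codebook.tags]
        )


@dataclass(frozen=True)
class NoiseModel:
    """Instrument artifact configuration on the calibrated intensity scale.

    level_means
        Cluster centers for levels 0..3 per channel; default (0, 1, 2, 3),
        the additive interpretation of the 2:1 probe concentration ratio.
    cluster_sd
        Gaussian scatter around the cluster center (default 0.05, giving
        cleanly separable clusters).
    baseline_offset
        Per-well additive constant applied after mixing.
    rain_fraction
        Probability that a positive channel value is drawn uniformly between
        its level mean and the next lower level mean instead.
    incomplete_hydrolysis_prob / incomplete_hydrolysis_factor
        Probability that a 2i contribution is attenuated, and the multiplier
        applied to it (default 0.75: level 2 renders at 1.5).
    """

    level_means: tuple[float, float, float, float] = (0.0, 1.0, 2.0, 3.0)
    cluster_sd: float = 0.05
    baseline_offset: float = 0.0
    rain_fraction: float = 0.0
    incomplete_hydrolysis_prob: float = 0.0
    incomplete_hydrolysis_factor: float = 0.75

    def __post_init__(self) -> None:
        means = tuple(float(m) for m in self.level_means)
        if len(means) != 4 or any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("level_means must be 4 strictly increasing values")
        object.__setattr__(self, "level_means", means)
        for p in (self.rain_fraction, self.incomplete_hydrolysis_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(cluster_sd=0.0)


@dataclass(frozen=True)
class SimulatedRun:
    """One simulated well: observed amplitudes plus the generating truth."""

    amplitudes: AmplitudeMatrix
    occupancy: np.ndarray  # bool (N, n_tags), column order = codebook order
    truth: TruthSpec

    @property
    def true_label_codes(self) -> np.ndarray:
        return true_label_codes(self.occupancy, self.truth.codebook)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def load_partitions(
    truth: TruthSpec, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Poisson-load molecules; return boolean occupancy (N x n_tags).

    Each tag occupies each partition independently with probability
    ``1 - exp(-copies/N)`` — the exact occupancy law for Poisson(copies)
    molecules placed uniformly and independently.
    """
    gen = _rng(truth.seed if rng is None else rng)
    lam = truth.copies_vector() / truth.partitions
    p = -np.expm1(-lam)
    return gen.random((truth.partitions, len(truth.codebook))) < p


def true_label_codes(occupancy: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Per-partition true union label as a 2-bit-per-channel integer code."""
    occupancy = np.asarray(occupancy, dtype=bool)
    bits = np.array([t.bits for t in codebook.tags])  # (T, C), values 0/1/2
    has1 = occupancy @ (bits == 1)  # counts of 1i contributors per channel
    has2 = occupancy @ (bits == 2)
    digits = (has1 > 0) * 1 + (has2 > 0) * 2
    weights = 4 ** np.arange(codebook.channels - 1, -1, -1)
    return digits @ weights


def render_signal(
    occupancy: np.ndarray,
    codebook: Codebook,
    noise: NoiseModel | None = None,
    crosstalk: CrosstalkMatrix | None = None,
    rng: np.random.Generator | int | None = None,
) -> AmplitudeMatrix:
    """Turn per-partition occupancy into an observed amplitude matrix.

    Per partition and channel: level = union digit of the occupying tags;
    intensity = level mean, with incomplete-hydrolysis attenuation of the 2i
    contribution and rain substitution applied, plus Gaussian scatter; then
    rows are mixed by the crosstalk matrix and the baseline offset is added.
    """
    noise = noise or NoiseModel()
    gen = _rng(rng)
    occupancy = np.asarray(occupancy, dtype=bool)
    if occupancy.shape[1] != len(codebook):
        raise ValueError("occupancy column count must match the codebook size")
    if crosstalk is not None and crosstalk.n_channels != codebook.channels:
        raise ValueError("crosstalk matrix channel count must match the codebook")

    bits = np.array([t.bits for t in codebook.tags])
    has1 = (occupancy @ (bits == 1)) > 0
    has2 = (occupancy @ (bits == 2)) > 0
    digits = has1 * 1 + has2 * 2  # (N, C) in 0..3

    means = np.asarray(noise.level_means)
    intensity = means[digits]

    if noise.incomplete_hydrolysis_prob > 0:
        # attenuate the 2i component: its contribution means[2] becomes
        # factor * means[2] (level 3 keeps its 1i part untouched)
        hit = has2 & (gen.random(digits.shape) < noise.incomplete_hydrolysis_prob)
        intensity = intensity - hit * (1.0 - noise.incomplete_hydrolysis_factor) * means[2]

    if noise.rain_fraction > 0:
        positive = digits > 0
        rainy = positive & (gen.random(digits.shape) < noise.rain_fraction)
        lower = means[np.maximum(digits - 1, 0)]
        upper = means[digits]
        u = gen.random(digits.shape)
        intensity = np.where(rainy, lower + u * (upper - lower), intensity)

    if noise.cluster_sd > 0:
        intensity = intensity + gen.normal(0.0, noise.cluster_sd, digits.shape)

    observed = crosstalk.mix(intensity) if crosstalk is not None else intensity
    observed = observed + noise.baseline_offset
    return AmplitudeMatrix(observed)


def simulate_run(
    truth: TruthSpec,
    noise: NoiseModel | None = None,
    crosstalk: CrosstalkMatrix | None = None,
) -> SimulatedRun:
    """Full well simulation, reproducible from ``truth.seed``."""
    gen = _rng(truth.seed)
    occupancy = load_partitions(truth, gen)
    amplitudes = render_signal(occupancy, truth.codebook, noise, crosstalk, gen)
    return SimulatedRun(amplitudes, occupancy, truth)
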