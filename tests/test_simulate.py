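"""Simulator: Poisson loading, signal rendering, artifacts, determinism."""

import numpy as np
import pytest

from dpcrmux.codebook import Codebook, TagSignature, enumerate_codebook
from dpcrmux.signal import CrosstalkMatrix, classify_partitions
from dpcrmux.simulate import (
    NoiseModel,
    TruthSpec,
    load_partitions,
    render_signal,
    simulate_run,
    true_label_codes,
)
from dpcrmux.studies import copresence_fraction


def _one_tag_codebook(sig: str) -> Codebook:
    t = TagSignature.from_string(sig)
    return Codebook(t.channels, 2, t.n_sites, (t,))


def test_zero_copies_gives_empty_partitions(cb32):
    truth = TruthSpec(cb32, {}, partitions=500, seed=0)
    occ = load_partitions(truth)
    assert occ.shape == (500, 32)
    assert not occ.any()


def test_empty_fraction_matches_poisson_limit():
    cb = _one_tag_codebook("1000")
    n = 26_000
    truth = TruthSpec(cb, {"1000": 10.0 * n}, partitions=n, seed=5)
    occ = load_partitions(truth)
    frac_empty = 1.0 - occ[:, 0].mean()
    expected = np.exp(-10.0)
    sd = np.sqrt(expected * (1 - expected) / n)
    assert abs(frac_empty - expected) < 5 * sd


def test_per_tag_occupancy_rate_converges(cb32):
    n = 26_000
    truth = TruthSpec(cb32, {t.name: 150.0 for t in cb32.tags}, partitions=n, seed=9)
    occ = load_partitions(truth)
    expected = -np.expm1(-150.0 / n)
    rates = occ.mean(axis=0)
    sd = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(rates - expected) < 5 * sd)


def test_copresence_rate_matches_closed_form(cb32):
    n = 26_000
    truth = TruthSpec(cb32, {t.name: 100.0 for t in cb32.tags}, partitions=n, seed=11)
    occ = load_partitions(truth)
    n_tags_present = occ.sum(axis=1)
    occupied = n_tags_present >= 1
    observed = (n_tags_present[occupied] >= 2).mean()
    expected = copresence_fraction(32, 100.0, n)
    # binomial error on ~3100 occupied partitions
    sd = np.sqrt(expected * (1 - expected) / occupied.sum())
    assert abs(observed - expected) < 5 * sd


def test_render_empty_noiseless_is_zero(cb32):
    occ = np.zeros((10, 32), dtype=bool)
    amp = render_signal(occ, cb32, NoiseModel.noiseless(), rng=0)
    assert np.all(amp.values == 0.0)
    assert amp.n_channels == 4


def test_render_single_tag_level_means():
    cb = _one_tag_codebook("0200")
    amp = render_signal(np.array([[True]]), cb, NoiseModel.noiseless(), rng=0)
    assert np.allclose(amp.values, [[0, 2, 0, 0]])


def test_render_incomplete_hydrolysis_attenuates_2i():
    cb = _one_tag_codebook("0012")
    noise = NoiseModel(cluster_sd=0.0, incomplete_hydrolysis_prob=1.0)
    amp = render_signal(np.array([[True]]), cb, noise, rng=0)
    assert np.allclose(amp.values, [[0, 0, 1, 1.5]])


def test_render_level3_is_additive():
    cb = Codebook(
        1, 2, 1, (TagSignature.from_string("1"), TagSignature.from_string("2"))
    )
    amp = render_signal(np.array([[True, True]]), cb, NoiseModel.noiseless(), rng=0)
    assert np.allclose(amp.values, [[3.0]])


def test_render_rain_falls_between_level_means():
    cb = _one_tag_codebook("0200")
    noise = NoiseModel(cluster_sd=0.0, rain_fraction=1.0)
    occ = np.ones((200, 1), dtype=bool)
    amp = render_signal(occ, cb, noise, rng=3)
    col = amp.values[:, 1]
    assert np.all((col >= 1.0) & (col <= 2.0))  # between level-1 and level-2 means
    assert col.std() > 0.1


def test_render_channel_mismatch_raises(cb32):
    occ = np.zeros((5, 32), dtype=bool)
    with pytest.raises(ValueError):
        render_signal(occ, cb32, crosstalk=CrosstalkMatrix.identity(3), rng=0)


def test_same_seed_is_bit_identical(cb32):
    truth = TruthSpec(cb32, {t.name: 50.0 for t in cb32.tags}, partitions=2000, seed=21)
    a = simulate_run(truth, NoiseModel(rain_fraction=0.05, incomplete_hydrolysis_prob=0.1))
    b = simulate_run(truth, NoiseModel(rain_fraction=0.05, incomplete_hydrolysis_prob=0.1))
    assert np.array_equal(a.amplitudes.values, b.amplitudes.values)
    assert np.array_equal(a.occupancy, b.occupancy)


def test_classify_of_noiseless_render_recovers_union_labels(cb32):
    """Loop-back: zero noise, identity crosstalk, zero baseline."""
    truth = TruthSpec(
        cb32, {t.name: 400.0 for t in cb32.tags}, partitions=5000, seed=33
    )
    run = simulate_run(truth, NoiseModel.noiseless())
    labels, _ = classify_partitions(run.amplitudes)
    weights = 4 ** np.arange(3, -1, -1)
    observed_codes = np.array([np.dot(l.levels, weights) for l in labels])
    assert np.array_equal(observed_codes, true_label_codes(run.occupancy, cb32))


def test_default_noise_classification_matches_occupancy(cb32):
    """>= 99% of occupied partitions get their occupancy-union label."""
    truth = TruthSpec(
        cb32, {t.name: 150.0 for t in cb32.tags}, partitions=26_000, seed=8
    )
    run = simulate_run(truth)  # default noise: cluster_sd 0.05
    labels, _ = classify_partitions(run.amplitudes)
    weights = 4 ** np.arange(3, -1, -1)
    observed = np.array([np.dot(l.levels, weights) for l in labels])
    true = run.true_label_codes
    occupied = run.occupancy.any(axis=1)
    assert (observed[occupied] == true[occupied]).mean() >= 0.99


def test_truth_spec_validation(cb32):
    with pytest.raises(KeyError):
        TruthSpec(cb32, {"not-a-tag": 10.0})
    with pytest.raises(ValueError):
        TruthSpec(cb32, {"1000": -1.0})
    with pytest.raises(ValueError):
        NoiseModel(level_means=(0, 2, 1, 3))
    with pytest.raises(ValueError):
        NoiseModel(rain_fraction=1.5)
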