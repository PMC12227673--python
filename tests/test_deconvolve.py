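"""Hierarchical Poisson deconvolution: exactness, oracle agreement, edges."""

import math

import numpy as np
import pytest

from dpcrmux.codebook import Codebook, TagSignature, enumerate_codebook
from dpcrmux.deconvolve import (
    DeconvolutionPlan,
    SaturatedReactionError,
    estimate_all,
    estimate_single_channel,
    label_probabilities,
    label_probability_vector,
)
from dpcrmux.signal import LabelCounts
from dpcrmux.simulate import TruthSpec, load_partitions, true_label_codes

from conftest import random_codebook


def _counts_from_probs(cb, lam, n=1_000_000):
    """Exact expected label counts (possibly non-integer) as LabelCounts-like
    vector for the plan API."""
    return label_probability_vector(cb, lam) * n


def test_single_channel_estimator_examples(cb32):
    counts = LabelCounts({"0000": 10_000, "1000": 1_000}, channels=4)
    lam = estimate_single_channel(counts, cb32.by_signature("1000"))
    assert lam == pytest.approx(math.log(1.1), rel=1e-12)
    zero = LabelCounts({"0000": 10_000}, channels=4)
    assert estimate_single_channel(zero, cb32.by_signature("1000")) == 0.0


def test_single_tag_codebook_reduces_to_classic_dpcr():
    """ln(1 + P_pos/P_0) == -ln(1 - P_pos/N) when P_0 = N - P_pos."""
    cb = Codebook(1, 2, 1, (TagSignature.from_string("1"),))
    n, pos = 20_000, 4_321
    counts = LabelCounts({"0": n - pos, "1": pos}, channels=1)
    res = estimate_all(counts, cb)
    classic = -math.log(1 - pos / n)
    assert res.estimates[0].lam == pytest.approx(classic, rel=1e-14)


def test_saturated_reaction_raises(cb32):
    counts = LabelCounts({"1000": 100}, channels=4)
    with pytest.raises(SaturatedReactionError):
        estimate_all(counts, cb32)


def test_three_tag_closed_form_recovery(cb3):
    """Spec worked example: exact expected counts from hand-derived label
    probabilities are inverted back to the generating lambdas."""
    la, lb, lc = 0.05, 0.08, 0.03  # 1000, 0100, 1100
    total = la + lb + lc
    n = 1_000_000
    p0 = n * math.exp(-total)
    p_1000 = p0 * math.expm1(la)
    p_0100 = p0 * math.expm1(lb)
    # P_1100/P_0 sums the five exact occupant sets {c}, {a,b}, {c,a}, {c,b},
    # {c,a,b}: expm1(lc)*exp(la)*exp(lb) + expm1(la)*expm1(lb)
    p_1100 = p0 * (
        math.expm1(lc) * math.exp(la) * math.exp(lb)
        + math.expm1(la) * math.expm1(lb)
    )
    counts_vec = {"0000": p0, "1000": p_1000, "0100": p_0100, "1100": p_1100}
    plan = DeconvolutionPlan(cb3)
    vec = np.zeros(256)
    w = 4 ** np.arange(3, -1, -1)
    for label, c in counts_vec.items():
        vec[int(np.dot([int(x) for x in label], w))] = c
    lam = plan.lambdas_from_codes(vec)
    by_sig = dict(zip(cb3.signature_strings, lam))
    assert by_sig["1000"] == pytest.approx(la, rel=1e-12)
    assert by_sig["0100"] == pytest.approx(lb, rel=1e-12)
    assert by_sig["1100"] == pytest.approx(lc, rel=1e-12)


def test_full_32plex_exact_recovery(cb32):
    gen = np.random.default_rng(2)
    lam = gen.uniform(0.005, 0.2, 32)
    vec = _counts_from_probs(cb32, lam)
    lam_hat = DeconvolutionPlan(cb32).lambdas_from_codes(vec)
    assert np.max(np.abs(lam_hat - lam) / lam) < 1e-10


def test_all_zero_counts_give_zero_lambdas(cb32):
    counts = LabelCounts({"0000": 26_000}, channels=4)
    res = estimate_all(counts, cb32)
    assert all(e.lam == 0.0 for e in res.estimates)
    assert res.total_copies == 0.0


def test_monotone_in_own_label_count(cb3):
    base = {"0000": 20_000, "1000": 800, "0100": 600, "1100": 300}
    lam1 = estimate_all(LabelCounts(base, 4), cb3).lambdas["1100"]
    bumped = dict(base, **{"1100": 400})
    lam2 = estimate_all(LabelCounts(bumped, 4), cb3).lambdas["1100"]
    assert lam2 > lam1


def test_negative_corrected_count_clamps_to_zero(cb3):
    # many 1000/0100 partitions but few 1100: E exceeds P -> lambda 0
    counts = LabelCounts(
        {"0000": 10_000, "1000": 3_000, "0100": 3_000, "1100": 500}, 4
    )
    res = estimate_all(counts, cb3)
    est = {e.signature: e for e in res.estimates}
    assert est["1100"].corrected == 0.0
    assert est["1100"].lam == 0.0
    assert est["1100"].expected > 500


def test_excluded_labels_reported(cb3):
    counts = LabelCounts(
        {"0000": 9_000, "1000": 500, "3000": 40, "0010": 7}, channels=4
    )
    res = estimate_all(counts, cb3)
    assert res.excluded == {"3000": 40, "0010": 7}
    assert res.n_excluded == 47


def test_intermediate_quantities_ordering(cb32):
    """P* <= P' <= P_L whenever the correction is non-negative."""
    gen = np.random.default_rng(3)
    lam = gen.uniform(0.01, 0.15, 32)
    vec = label_probability_vector(cb32, lam) * 26_000
    counts = {
        sig: vec[int(np.dot([int(c) for c in sig], 4 ** np.arange(3, -1, -1)))]
        for sig in cb32.signature_strings
    }
    labels = {k: int(round(v)) for k, v in counts.items() if v >= 1}
    labels["0000"] = int(vec[0])
    res = estimate_all(LabelCounts(labels, 4), cb32)
    for e in res.estimates:
        assert e.corrected_final <= e.corrected + 1e-9
        assert e.corrected <= e.count + 1e-9


def test_label_probabilities_single_and_pair():
    cb1 = Codebook(1, 2, 1, (TagSignature.from_string("1"),))
    lam = 0.3
    probs = label_probabilities(cb1, [lam])
    assert probs["0"] == pytest.approx(math.exp(-lam))
    assert probs["1"] == pytest.approx(-math.expm1(-lam))

    cb2 = Codebook(
        2, 2, 1, (TagSignature.from_string("10"), TagSignature.from_string("01"))
    )
    la, lb = 0.2, 0.4
    probs = label_probabilities(cb2, [la, lb])
    assert probs["11"] == pytest.approx(math.expm1(-la) * math.expm1(-lb))


def test_label_probabilities_sum_to_one_random_codebooks():
    gen = np.random.default_rng(5)
    for _ in range(20):
        cb = random_codebook(gen)
        lam = gen.uniform(0, 0.3, len(cb))
        assert label_probability_vector(cb, lam).sum() == pytest.approx(1.0)


def test_label_probabilities_match_simulation(cb32):
    """Monte Carlo occupancy frequencies agree with the exact distribution."""
    n = 26_000
    copies = 120.0
    truth = TruthSpec(cb32, {t.name: copies for t in cb32.tags}, partitions=n, seed=17)
    occ = load_partitions(truth)
    codes = true_label_codes(occ, cb32)
    freq = np.bincount(codes, minlength=256) / n
    probs = label_probability_vector(cb32, np.full(32, copies / n))
    for code in np.argsort(probs)[::-1][:10]:  # ten most probable labels
        sd = math.sqrt(probs[code] * (1 - probs[code]) / n)
        assert abs(freq[code] - probs[code]) < 3.5 * sd + 1e-12


def test_random_codebook_exact_recovery_property():
    """Consistency on exact expected counts for random geometries."""
    gen = np.random.default_rng(11)
    for _ in range(25):
        cb = random_codebook(gen)
        lam = gen.uniform(0.001, 0.2, len(cb))
        vec = _counts_from_probs(cb, lam)
        lam_hat = DeconvolutionPlan(cb).lambdas_from_codes(vec)
        assert np.max(np.abs(lam_hat - lam) / np.maximum(lam, 1e-12)) < 1e-10
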