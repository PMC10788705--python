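"""Unit and gradient tests for the uncertainty-aware training objectives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calaware._autodiff import Tensor
from calaware.calibration import PredictionSet, bin_predictions, ece, reliability_profile
from calaware.losses import (STRATEGIES, LossHyperparams, TrainingBatch, avuc_loss,
                             composite_loss, confidence_weights, mmce_loss,
                             paired_confidence_loss, probability_loss, soft_ece_loss,
                             strategy_loss, weighted_classifier_loss)


def batch_from(p_pos, labels):
    p_pos = np.asarray(p_pos, dtype=float)
    return TrainingBatch.from_probs(np.column_stack([1 - p_pos, p_pos]), labels)


def random_batch(rng, n=8):
    return TrainingBatch.from_logits(Tensor(rng.normal(0, 1.5, (n, 2))),
                                     rng.integers(0, 2, n))


# -- hyperparameters ---------------------------------------------------------

def test_published_preset_values():
    hp = LossHyperparams.preset("baseline", "crt")
    assert (hp.lambda_kl, hp.lambda_c) == (0.001, 3.0)
    hp = LossHyperparams.preset("paired_confidence", "cad")
    assert (hp.lambda_kl, hp.lambda_c, hp.lambda_n, hp.mu) == (0.1, 1.5, 0.4, 0.8)
    assert LossHyperparams.preset("soft_ece", "crt").temperature == 0.1
    assert LossHyperparams.preset("soft_ece", "cad").temperature == 0.01
    assert LossHyperparams.preset("soft_ece", "crt").n_bins == 15


def test_degenerate_confidence_weight_floor_warns():
    with pytest.warns(UserWarning, match="floor"):
        LossHyperparams.preset("confidence_weight", "cad")


def test_hyperparams_validation():
    with pytest.raises(ValueError):
        LossHyperparams(temperature=0.0)
    with pytest.raises(ValueError):
        LossHyperparams(lambda_n=-1.0)
    with pytest.raises(ValueError):
        LossHyperparams(p=0.5)


# -- composite ---------------------------------------------------------------

def test_composite_reduces_to_baseline_without_strategy_term():
    hp = LossHyperparams(lambda_kl=0.001, lambda_c=3.0, lambda_n=5.0)
    assert composite_loss(1.0, 2.0, 0.5, hp).item() == pytest.approx(1.0 + 0.002 + 1.5)
    assert composite_loss(0.0, 0.0, 0.0, hp).item() == 0.0


def test_composite_adds_weighted_strategy_term():
    hp = LossHyperparams(lambda_kl=0.0, lambda_c=1.0, lambda_n=0.5)
    assert composite_loss(1.0, 9.0, 1.0, hp, extra=4.0).item() == pytest.approx(4.0)


def test_composite_names_non_finite_term():
    hp = LossHyperparams()
    with pytest.raises(FloatingPointError, match="kl"):
        composite_loss(1.0, np.inf, 0.5, hp)


# -- paired confidence -------------------------------------------------------

def test_paired_confidence_single_pair():
    # one FP at P(pos)=0.8 against one TP at P(pos)=0.6, margin 0.1
    b = batch_from([0.8, 0.6], [0, 1])
    assert paired_confidence_loss(b, 0.1).item() == pytest.approx(0.3)


def test_paired_confidence_zero_when_margin_met():
    b = batch_from([0.7, 0.9], [0, 1])  # FP 0.7 vs TP 0.9
    assert paired_confidence_loss(b, 0.1).item() == 0.0


def test_paired_confidence_zero_without_incorrect_predictions():
    b = batch_from([0.9, 0.1, 0.8], [1, 0, 1])
    assert paired_confidence_loss(b, 0.5).item() == 0.0


def test_paired_confidence_normalised_by_pair_count():
    # two FPs, two TPs: four pairs in the positive class
    b = batch_from([0.8, 0.7, 0.6, 0.9], [0, 0, 1, 1])
    expected = np.mean([max(0, pi - pj + 0.1)
                        for pi in (0.8, 0.7) for pj in (0.6, 0.9)])
    assert paired_confidence_loss(b, 0.1).item() == pytest.approx(expected)


# -- probability loss --------------------------------------------------------

def test_probability_loss_hand_example():
    # G wrong-class probs {0.3, 0.5}; Gbar wrong-class prob {0.2}
    b = batch_from([0.7, 0.5, 0.2], [1, 1, 0])
    assert probability_loss(b).item() == pytest.approx(0.4 + 0.2)


def test_probability_loss_bounds_and_single_class():
    assert probability_loss(batch_from([1.0, 0.0], [1, 0])).item() == 0.0
    assert probability_loss(batch_from([0.0, 1.0], [1, 0])).item() == pytest.approx(2.0)
    # single-class batch: absent class contributes nothing
    assert probability_loss(batch_from([0.9, 0.8], [1, 1])).item() == pytest.approx(
        (0.1 + 0.2) / 2)


def test_probability_loss_monotone_in_wrong_class_probability():
    vals = [probability_loss(batch_from([p, 0.2], [1, 0])).item()
            for p in (0.9, 0.7, 0.5)]
    assert vals[0] < vals[1] < vals[2]


# -- confidence weights ------------------------------------------------------

def test_confidence_weight_contract():
    w = confidence_weights([0.0, 1.0, 0.75], [1, 1, 0], w=0.2)
    assert w.raw == pytest.approx([1.0, 0.0, 0.75])
    assert w.scaled == pytest.approx([1.0, 0.2, 0.8])
    assert np.all(w.scaled == (1 - 0.2) * w.raw + 0.2)


def test_confidence_weight_rejects_invalid_c():
    with pytest.raises(ValueError):
        confidence_weights([1.2], [1], w=0.1)


def test_weighted_classifier_loss_identity_and_linearity():
    b = batch_from([0.8, 0.8], [1, 1])
    from calaware.losses import SampleWeights
    unit = SampleWeights(raw=np.ones(2), scaled=np.ones(2))
    assert weighted_classifier_loss(b, unit).item() == pytest.approx(
        b.cross_entropy().item())
    lopsided = SampleWeights(raw=np.array([2.0, 0.0]), scaled=np.array([2.0, 0.0]))
    single = batch_from([0.8], [1])
    assert weighted_classifier_loss(b, lopsided).item() == pytest.approx(
        single.cross_entropy().item())
    with pytest.raises(ValueError, match="aligned"):
        weighted_classifier_loss(b, SampleWeights(np.ones(3), np.ones(3)))


# -- AvUC --------------------------------------------------------------------

def test_avuc_hard_counts():
    # entropies: conf 0.99 -> ~0.056 nats (certain at thr 0.5); 0.55 -> ~0.688
    p = [0.99, 0.99, 0.55, 0.55, 0.55, 0.01]
    g = [1, 1, 1, 1, 1, 1]
    # correct: first five (pred 1) except last (pred 0, wrong, certain)
    b = batch_from(p, g)
    # |T∩U|=3 (0.55s), |T̄∩Ū|=1 (0.01), |T∩Ū|=2, |T̄∩U|=0
    expected = np.log(1 + (3 + 1) / (2 + 0))
    assert avuc_loss(b, 0.5, "hard").item() == pytest.approx(expected)


def test_avuc_zero_when_accurate_and_certain():
    b = batch_from([0.99, 0.01], [1, 0])
    assert avuc_loss(b, 1.0, "hard").item() == 0.0
    assert avuc_loss(b, 1.0, "soft").item() == 0.0


def test_avuc_soft_tracks_hard_on_saturated_batches():
    # accurate-certain (confidence near 1, tiny entropy) plus
    # inaccurate-uncertain (confidence near 0.5) samples: both cells sit in
    # the denominator, the proxies saturate, and soft == hard == 0
    rng = np.random.default_rng(12)
    for _ in range(10):
        n = 12
        certain = rng.random(n) < 0.6
        conf = np.where(certain, rng.uniform(0.99, 0.999, n),
                        rng.uniform(0.52, 0.58, n))
        labels = rng.integers(0, 2, n)
        # certain samples are correct, uncertain ones incorrect
        p_pos = np.where(labels == 1, np.where(certain, conf, 1 - conf),
                         np.where(certain, 1 - conf, conf))
        b = batch_from(p_pos, labels)
        hard = avuc_loss(b, 0.4, "hard").item()
        soft = avuc_loss(b, 0.4, "soft").item()
        assert soft == pytest.approx(hard, abs=1e-2)


# -- soft ECE ----------------------------------------------------------------

def test_soft_ece_zero_when_soft_profile_calibrated():
    # all samples share one confidence; accuracy fraction equals it
    b = batch_from([0.8, 0.8, 0.8, 0.8, 0.8], [1, 1, 1, 1, 0])
    assert soft_ece_loss(b, 15, 0.1, 1.0).item() == pytest.approx(0.0, abs=1e-9)


def test_soft_ece_converges_to_hard_ece():
    rng = np.random.default_rng(4)
    for _ in range(5):
        n = 20
        conf = rng.uniform(0.51, 0.99, n)
        # keep confidences away from the 15-bin edges
        edges = np.arange(1, 15) / 15
        conf = conf[np.min(np.abs(conf[:, None] - edges[None]), axis=1) > 0.02]
        labels = rng.integers(0, 2, conf.size)
        p_pos = np.where(rng.random(conf.size) < 0.5, conf, 1 - conf)
        ps = PredictionSet.from_positive_probs(p_pos, labels)
        hard = ece(reliability_profile(ps, bin_predictions(ps, 15, "equal_width")))
        b = batch_from(p_pos, labels)
        assert soft_ece_loss(b, 15, 1e-4, 1.0).item() == pytest.approx(hard, abs=1e-3)


# -- MMCE --------------------------------------------------------------------

def mmce_brute_force(p_pos, labels, width=0.4):
    """Double loop over all ordered pairs of the three kernel sums."""
    p_pos = np.asarray(p_pos, dtype=float)
    labels = np.asarray(labels)
    pred = (p_pos > 0.5).astype(int)
    r = np.maximum(p_pos, 1 - p_pos)
    correct = pred == labels
    n = len(labels)
    k = lambda a, b: np.exp(-abs(a - b) / width)
    inc = [i for i in range(n) if not correct[i]]
    cor = [i for i in range(n) if correct[i]]
    total = 0.0
    if inc:
        total += sum(r[i] * r[j] * k(r[i], r[j]) for i in inc for j in inc) / len(inc) ** 2
    if cor:
        total += sum((1 - r[i]) * (1 - r[j]) * k(r[i], r[j])
                     for i in cor for j in cor) / n ** 2
    if inc and cor:
        total -= 2 * sum((1 - r[i]) * r[j] * k(r[i], r[j])
                         for i in cor for j in inc) / (len(inc) * n)
    return total


def test_mmce_matches_pairwise_brute_force():
    p = [0.9, 0.2, 0.7]   # confidences 0.9, 0.8, 0.7; last one incorrect
    g = [1, 1, 1]
    b = batch_from(p, g)
    assert mmce_loss(b, 0.4).item() == pytest.approx(mmce_brute_force(p, g), abs=1e-12)


def test_mmce_zero_for_perfect_confident_batch():
    b = batch_from([1.0, 0.0, 1.0], [1, 0, 1])
    assert mmce_loss(b, 0.4).item() == pytest.approx(0.0, abs=1e-12)


def test_mmce_permutation_invariant_and_nonnegative():
    rng = np.random.default_rng(9)
    for _ in range(10):
        n = 10
        p = rng.random(n)
        g = rng.integers(0, 2, n)
        v1 = mmce_loss(batch_from(p, g), 0.4).item()
        perm = rng.permutation(n)
        v2 = mmce_loss(batch_from(p[perm], g[perm]), 0.4).item()
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert v1 >= -1e-9


# -- generic properties ------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_losses_nonnegative_and_finite_on_random_batches(seed):
    rng = np.random.default_rng(seed)
    b = random_batch(rng)
    hp = LossHyperparams()
    for strategy in STRATEGIES:
        extra = strategy_loss(strategy, b, hp)
        if extra is not None:
            v = extra.item()
            assert np.isfinite(v)
            assert v >= -1e-9


def central_difference_check(fn, logits, labels, h=1e-6):
    t = Tensor(logits.copy(), requires_grad=True)
    loss = fn(TrainingBatch.from_logits(t, labels))
    loss.backward()
    analytic = t.grad
    numeric = np.zeros_like(logits)
    for idx in np.ndindex(*logits.shape):
        e = np.zeros_like(logits)
        e[idx] = h
        up = fn(TrainingBatch.from_logits(Tensor(logits + e), labels)).item()
        dn = fn(TrainingBatch.from_logits(Tensor(logits - e), labels)).item()
        numeric[idx] = (up - dn) / (2 * h)
    denom = np.maximum(np.abs(analytic) + np.abs(numeric), 1e-6)
    return np.max(np.abs(analytic - numeric) / denom)


DIFFERENTIABLE = {
    "classifier_ce": lambda b: b.cross_entropy(),
    "paired_confidence": lambda b: paired_confidence_loss(b, 0.2),
    "probability": probability_loss,
    "soft_ece": lambda b: soft_ece_loss(b, 15, 0.1, 1.0),
    "mmce": lambda b: mmce_loss(b, 0.4),
    "avuc_soft": lambda b: avuc_loss(b, 0.5, "soft"),
}


@pytest.mark.parametrize("name", sorted(DIFFERENTIABLE))
def test_gradients_match_central_differences(name):
    import zlib
    rng = np.random.default_rng(zlib.crc32(name.encode()))
    fn = DIFFERENTIABLE[name]
    for _ in range(5):
        logits = rng.normal(0, 1.5, (8, 2))
        labels = rng.integers(0, 2, 8)
        assert central_difference_check(fn, logits, labels) <= 1e-4
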