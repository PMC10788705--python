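"""Calibration metric unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import calaware.calibration as calib
from calaware.calibration import (BinPartition, ConfusionCounts, PredictionSet,
                                  ReliabilityProfile, adaptive_ece, bin_predictions,
                                  brier_score, classification_summary, confusion_counts,
                                  ece, mce, mcnemar_test, overconfidence_error,
                                  reliability_profile)

from conftest import random_prediction_set


# -- PredictionSet -----------------------------------------------------------

def test_prediction_set_derives_argmax_and_confidence():
    ps = PredictionSet(np.array([[0.3, 0.7], [0.8, 0.2], [0.5, 0.5]]), [1, 0, 1])
    assert ps.pred_label.tolist() == [1, 0, 0]  # tie -> class 0
    assert np.allclose(ps.confidence, [0.7, 0.8, 0.5])
    assert ps.correct.tolist() == [True, True, False]


@pytest.mark.parametrize("probs, labels, err", [
    (np.empty((0, 2)), [], "empty"),
    ([[0.3, 0.8]], [0], "sum to 1"),
    ([[0.5, 0.5]], [2], "labels"),
    ([[1.2, -0.2]], [0], "outside"),
])
def test_prediction_set_rejects_invalid_inputs(probs, labels, err):
    with pytest.raises(ValueError, match=err):
        PredictionSet(np.asarray(probs, dtype=float), labels)


# -- binning -----------------------------------------------------------------

def test_equal_width_binning_matches_ceiling_rule():
    ps = PredictionSet.from_positive_probs([0.52, 0.61, 0.93], [1, 1, 1])
    assert bin_predictions(ps, 15, "equal_width").assignment.tolist() == [8, 10, 14]


def test_adaptive_binning_splits_equal_masses_in_rank_order():
    ps = PredictionSet.from_positive_probs([0.6, 0.7, 0.8, 0.9], [1, 1, 1, 1])
    assert bin_predictions(ps, 2, "adaptive").assignment.tolist() == [1, 1, 2, 2]


def test_adaptive_remainder_goes_to_lowest_rank_bins():
    ps = PredictionSet.from_positive_probs([0.5, 0.6, 0.7, 0.8, 0.9], [1] * 5)
    part = bin_predictions(ps, 2, "adaptive")
    assert np.bincount(part.assignment)[1:].tolist() == [3, 2]


@pytest.mark.parametrize("scheme", ["equal_width", "adaptive"])
def test_single_bin_holds_every_sample(scheme):
    rng = np.random.default_rng(0)
    ps = random_prediction_set(rng, 20)
    assert (bin_predictions(ps, 1, scheme).assignment == 1).all()


def test_binning_errors():
    ps = PredictionSet.from_positive_probs([0.7, 0.8], [1, 1])
    with pytest.raises(ValueError, match="adaptive"):
        bin_predictions(ps, 5, "adaptive")
    with pytest.raises(ValueError):
        bin_predictions(ps, 0, "equal_width")
    with pytest.raises(ValueError, match="scheme"):
        bin_predictions(ps, 2, "quantile")


def test_confidence_zero_would_map_to_bin_one():
    # binary max-prob confidence cannot fall below 0.5, but the edge rule
    # is defined on all of [0, 1]: check it through the partition contract
    part = BinPartition(scheme="equal_width", n_bins=15, assignment=np.array([1]))
    assert part.assignment[0] == 1


# -- reliability profile -----------------------------------------------------

def test_profile_hand_example_and_empty_bins():
    ps = PredictionSet.from_positive_probs([0.8, 0.8], [1, 0])  # one correct
    prof = reliability_profile(ps, bin_predictions(ps, 15, "equal_width"))
    m = 11  # ceil(0.8 * 15) - 1
    assert prof.counts[m] == 2
    assert prof.accuracy[m] == pytest.approx(0.5)
    assert prof.mean_confidence[m] == pytest.approx(0.8)
    assert prof.counts.sum() == 2
    assert not prof.nonempty[0]


def test_profile_mismatched_lengths_error():
    ps = PredictionSet.from_positive_probs([0.8, 0.9], [1, 0])
    part = BinPartition("equal_width", 2, np.array([1]))
    with pytest.raises(ValueError, match="cover"):
        reliability_profile(ps, part)


# -- scalar metrics ----------------------------------------------------------

def _profile(counts, acc, conf):
    return ReliabilityProfile(np.asarray(counts), np.asarray(acc, dtype=float),
                              np.asarray(conf, dtype=float), "equal_width")


def test_ece_weighted_gap():
    assert ece(_profile([4], [0.5], [0.9])) == pytest.approx(0.4)
    assert ece(_profile([1, 3], [0.7, 0.8], [0.9, 0.8])) == pytest.approx(0.05)


def test_ece_zero_when_acc_equals_conf():
    assert ece(_profile([5, 5], [0.6, 0.9], [0.6, 0.9])) == 0.0


def test_overconfidence_error_values():
    assert overconfidence_error(_profile([2], [0.5], [0.8])) == pytest.approx(0.24)
    assert overconfidence_error(_profile([2], [0.9], [0.8])) == 0.0


def test_mce_is_max_gap_and_excludes_empty_bins():
    prof = _profile([1, 0, 2, 3], [0.9, np.nan, 0.4, 0.8],
                    [0.95, np.nan, 0.7, 0.9])
    assert mce(prof) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        mce(_profile([0, 0], [np.nan, np.nan], [np.nan, np.nan]))


def test_adaptive_ece_hand_example():
    ps = PredictionSet.from_positive_probs([0.6, 0.3, 0.8, 0.9], [1, 1, 1, 1])
    # confidences {0.6, 0.7, 0.8, 0.9}; second sample incorrect
    assert adaptive_ece(ps, 2) == pytest.approx(0.15)


def test_adaptive_ece_degenerates_to_mean_gap_at_m_equals_n():
    rng = np.random.default_rng(3)
    ps = random_prediction_set(rng, 25)
    expected = np.mean(np.abs(ps.correct.astype(float) - ps.confidence))
    assert adaptive_ece(ps, len(ps)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p_pos, label, value", [
    (1.0, 1, 0.0),    # perfect confident correct
    (0.5, 1, 0.5),    # maximal uncertainty
    (1.0, 0, 2.0),    # maximally wrong
])
def test_brier_vector_variant(p_pos, label, value):
    ps = PredictionSet.from_positive_probs([p_pos], [label])
    assert brier_score(ps) == pytest.approx(value)
    assert brier_score(ps, variant="positive") == pytest.approx(value / 2)


# -- classification summary --------------------------------------------------

def test_classification_summary_arithmetic():
    sen, spe, bacc = classification_summary(ConfusionCounts(tp=7, fp=4, tn=6, fn=3))
    assert (sen, spe, bacc) == pytest.approx((0.7, 0.6, 0.65))


def test_bacc_invariant_under_label_inversion():
    ps = PredictionSet.from_positive_probs([0.8, 0.3, 0.9, 0.2, 0.7], [1, 0, 0, 0, 1])
    inv = PredictionSet.from_positive_probs(1 - ps.probs[:, 1], 1 - ps.true_label)
    s1 = classification_summary(confusion_counts(ps))
    s2 = classification_summary(confusion_counts(inv))
    assert s1[2] == pytest.approx(s2[2])
    assert (s1[0], s1[1]) == pytest.approx((s2[1], s2[0]))


def test_classification_summary_names_missing_class():
    with pytest.raises(ValueError, match="positive"):
        classification_summary(ConfusionCounts(tp=0, fp=1, tn=3, fn=0))
    with pytest.raises(ValueError, match="negative"):
        classification_summary(ConfusionCounts(tp=2, fp=0, tn=0, fn=1))


# -- McNemar -----------------------------------------------------------------

def _sets_with_discordance(b, c, n_extra=5):
    """Two prediction sets with exactly b and c discordant pairs."""
    n = b + c + n_extra
    labels = np.ones(n, dtype=int)
    pa = np.ones(n); pb = np.ones(n)
    pa[:b] = 0.9; pb[:b] = 0.1           # a right, b wrong
    pa[b:b + c] = 0.1; pb[b:b + c] = 0.9  # a wrong, b right
    pa[b + c:] = 0.8; pb[b + c:] = 0.8
    return (PredictionSet.from_positive_probs(pa, labels),
            PredictionSet.from_positive_probs(pb, labels))


def test_mcnemar_symmetric_discordance_gives_p_one():
    a, b = _sets_with_discordance(4, 4)
    _, p, sig = mcnemar_test(a, b)
    assert p == pytest.approx(1.0)
    assert not sig


def test_mcnemar_exact_matches_binomial_oracle():
    a, b = _sets_with_discordance(10, 2)
    _, p, sig = mcnemar_test(a, b)
    oracle = 2 * stats.binom.cdf(2, 12, 0.5)
    assert p == pytest.approx(oracle, abs=1e-10)
    assert p == pytest.approx(0.0386, abs=5e-4)
    assert sig


def test_mcnemar_identical_predictions_not_significant():
    rng = np.random.default_rng(5)
    ps = random_prediction_set(rng, 30)
    _, p, sig = mcnemar_test(ps, ps)
    assert p == 1.0 and not sig


def test_mcnemar_rejects_mismatched_ground_truth():
    a = PredictionSet.from_positive_probs([0.8, 0.2], [1, 0])
    b = PredictionSet.from_positive_probs([0.8, 0.2], [0, 1])
    with pytest.raises(ValueError, match="same samples"):
        mcnemar_test(a, b)


# -- properties --------------------------------------------------------------

@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(2, 15))
def test_metric_ranges_order_and_permutation_invariance(seed, m):
    rng = np.random.default_rng(seed)
    ps = random_prediction_set(rng)
    prof = reliability_profile(ps, bin_predictions(ps, m, "equal_width"))
    e, o, x, b = ece(prof), overconfidence_error(prof), mce(prof), brier_score(ps)
    assert 0 <= o <= e <= x <= 1
    assert 0 <= b <= 2
    perm = rng.permutation(len(ps))
    ps2 = PredictionSet(ps.probs[perm], ps.true_label[perm])
    prof2 = reliability_profile(ps2, bin_predictions(ps2, m, "equal_width"))
    assert ece(prof2) == pytest.approx(e, abs=1e-12)
    assert overconfidence_error(prof2) == pytest.approx(o, abs=1e-12)
    assert mce(prof2) == pytest.approx(x, abs=1e-12)
    assert brier_score(ps2) == pytest.approx(b, abs=1e-12)
    assert adaptive_ece(ps2, min(m, len(ps2))) == pytest.approx(
        adaptive_ece(ps, min(m, len(ps))), abs=1e-12)


# -- exports -----------------------------------------------------------------

def test_report_writers_round_trip(tmp_path):
    import json
    rng = np.random.default_rng(1)
    ps = random_prediction_set(rng, 40)
    prof = reliability_profile(ps, bin_predictions(ps, 10, "equal_width"))
    payload = json.loads(calib.reliability_to_json(prof))
    assert payload["n"] == 40 and sum(payload["counts"]) == 40
    assert len(payload["bin_edges"]) == 11
    table = calib.reliability_to_table(prof)
    assert len(table.splitlines()) == 11  # header + one row per bin
    path = tmp_path / "metrics.csv"
    calib.write_metrics_csv(path, {"baseline": {"ECE": ece(prof)}})
    assert "baseline,ECE" in path.read_text()
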