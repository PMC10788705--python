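"""Calibration and classification metrics for binary probabilistic classifiers.

The central container is :class:`PredictionSet` (per-sample class
probabilities, labels and confidences). Confidence binning comes in two
flavours — equal-width bins on [0, 1] and adaptive (equal-mass, rank-based)
bins — and backs the calibration metrics:

* ECE, the bin-weighted mean absolute gap between per-bin accuracy and
  per-bin mean confidence;
* AECE, ECE over adaptive bins;
* overconfidence error (OE), a confidence-weighted penalty applied only
  where confidence exceeds accuracy;
* MCE, the largest per-bin gap;
* the Brier score.

Classification summaries (sensitivity/specificity/balanced accuracy) and
McNemar's paired test complete the evaluation suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "PredictionSet",
    "BinPartition",
    "ReliabilityProfile",
    "ConfusionCounts",
    "bin_predictions",
    "reliability_profile",
    "ece",
    "adaptive_ece",
    "overconfidence_error",
    "mce",
    "brier_score",
    "classification_summary",
    "confusion_counts",
    "mcnemar_test",
    "metric_suite",
    "write_metrics_csv",
    "reliability_to_json",
    "reliability_to_table",
]

Scheme = Literal["equal_width", "adaptive"]

#: Default number of confidence bins for ECE-style metrics.
DEFAULT_BINS = 15


@dataclass(frozen=True)
class PredictionSet:
    """Per-sample binary class probabilities with ground-truth labels.

    ``probs`` has shape (n, 2) with rows summing to 1; ``true_label`` is 0/1.
    ``pred_label`` is the argmax class (ties predict class 0) and
    ``confidence`` the probability of the predicted class, in [0.5, 1].
    """

    probs: np.ndarray
    true_label: np.ndarray
    pred_label: np.ndarray = field(init=False)
    confidence: np.ndarray = field(init=False)

    def __post_init__(self):
        probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        labels = np.asarray(self.true_label, dtype=int).ravel()
        if probs.shape[0] == 0:
            raise ValueError("empty prediction set")
        if probs.shape[1] != 2:
            raise ValueError(f"binary classifier expected (n, 2) probabilities, got {probs.shape}")
        if probs.shape[0] != labels.shape[0]:
            raise ValueError("probs and true_label length mismatch")
        if np.any(probs < -1e-9) or np.any(probs > 1 + 1e-9):
            raise ValueError("probabilities outside [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")
        if not np.all(np.isin(labels, [0, 1])):
            raise ValueError("true labels must be 0/1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "true_label", labels)
        # tie (0.5, 0.5) -> class 0, deterministically
        object.__setattr__(self, "pred_label", (probs[:, 1] > probs[:, 0]).astype(int))
        object.__setattr__(self, "confidence", probs.max(axis=1))

    @classmethod
    def from_positive_probs(cls, p_pos, true_label) -> "PredictionSet":
        p_pos = np.asarray(p_pos, dtype=float).ravel()
        return cls(np.column_stack([1.0 - p_pos, p_pos]), true_label)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def correct(self) -> np.ndarray:
        """Boolean mask of correctly classified samples (the set T)."""
        return self.pred_label == self.true_label


@dataclass(frozen=True)
class BinPartition:
    """Assignment of each sample to one of M confidence bins (1-based)."""

    scheme: Scheme
    n_bins: int
    assignment: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if a.size and (a.min() < 1 or a.max() > self.n_bins):
            raise ValueError("bin assignment outside [1, n_bins]")
        object.__setattr__(self, "assignment", a)


@dataclass(frozen=True)
class ReliabilityProfile:
    """Per-bin (count, mean accuracy, mean confidence) records.

    Empty bins carry count 0 and NaN accuracy/confidence; they contribute
    nothing to ECE/OE and are excluded from MCE. This is the exportable data
    behind a reliability diagram.
    """

    counts: np.ndarray
    accuracy: np.ndarray
    mean_confidence: np.ndarray
    scheme: Scheme
    n: int = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        acc = np.asarray(self.accuracy, dtype=float)
        conf = np.asarray(self.mean_confidence, dtype=float)
        if not (counts.shape == acc.shape == conf.shape):
            raise ValueError("per-bin arrays must share one shape")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "accuracy", acc)
        object.__setattr__(self, "mean_confidence", conf)
        object.__setattr__(self, "n", int(counts.sum()))

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def bin_predictions(preds: PredictionSet, n_bins: int = DEFAULT_BINS,
                    scheme: Scheme = "equal_width") -> BinPartition:
    """Assign samples to M confidence bins.

    Equal-width bins are half-open [lo, hi) on [0, 1] with the last bin
    closed, i.e. confidence c lands in bin ⌈c·M⌉ (c = 0 in bin 1). Adaptive
    bins are contiguous in confidence rank order (stable ties) with sizes
    differing by at most one; the remainder n mod M goes to the lowest-rank
    bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = len(preds)
    conf = preds.confidence
    if scheme == "equal_width":
        assignment = np.maximum(np.ceil(conf * n_bins), 1).astype(int)
        assignment = np.minimum(assignment, n_bins)
    elif scheme == "adaptive":
        if n_bins > n:
            raise ValueError(f"adaptive binning needs n_bins <= n ({n_bins} > {n})")
        order = np.argsort(conf, kind="stable")
        base, rem = divmod(n, n_bins)
        sizes = np.full(n_bins, base)
        sizes[:rem] += 1
        assignment = np.empty(n, dtype=int)
        assignment[order] = np.repeat(np.arange(1, n_bins + 1), sizes)
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    return BinPartition(scheme=scheme, n_bins=n_bins, assignment=assignment)


def reliability_profile(preds: PredictionSet, partition: BinPartition) -> ReliabilityProfile:
    """Per-bin counts, mean accuracies and mean confidences."""
    if len(preds) != partition.assignment.shape[0]:
        raise ValueError("partition does not cover the prediction set")
    m = partition.n_bins
    idx = partition.assignment - 1
    counts = np.bincount(idx, minlength=m)
    correct = preds.correct.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.bincount(idx, weights=correct, minlength=m) / counts
        conf = np.bincount(idx, weights=preds.confidence, minlength=m) / counts
    return ReliabilityProfile(counts=counts, accuracy=acc, mean_confidence=conf,
                              scheme=partition.scheme)


def _weights(profile: ReliabilityProfile) -> np.ndarray:
    if profile.n == 0:
        raise ValueError("profile has no samples")
    return profile.counts / profile.n


def ece(profile: ReliabilityProfile) -> float:
    """Expected calibration error: Σ_m (|B_m|/n)·|acc(B_m) − conf(B_m)|."""
    w = _weights(profile)
    gap = np.abs(profile.accuracy - profile.mean_confidence)
    return float(np.sum(w[profile.nonempty] * gap[profile.nonempty]))


def adaptive_ece(preds: PredictionSet, n_bins: int = DEFAULT_BINS) -> float:
    """ECE under the adaptive (equal-mass) binning scheme."""
    return ece(reliability_profile(preds, bin_predictions(preds, n_bins, "adaptive")))


def overconfidence_error(profile: ReliabilityProfile) -> float:
    """OE: Σ_m (|B_m|/n)·conf(B_m)·max(conf(B_m) − acc(B_m), 0)."""
    w = _weights(profile)
    over = np.maximum(profile.mean_confidence - profile.accuracy, 0.0)
    term = profile.mean_confidence * over
    return float(np.sum(w[profile.nonempty] * term[profile.nonempty]))


def mce(profile: ReliabilityProfile) -> float:
    """Maximum calibration error over nonempty bins."""
    mask = profile.nonempty
    if not mask.any():
        raise ValueError("all bins are empty")
    return float(np.max(np.abs(profile.accuracy[mask] - profile.mean_confidence[mask])))


def brier_score(preds: PredictionSet, variant: Literal["vector", "positive"] = "vector") -> float:
    """Mean squared distance between probability vector and one-hot outcome.

    The default ``vector`` variant sums the squared error over both classes
    (range [0, 2], the standard multiclass Brier score); ``positive`` uses
    only the positive-class probability (range [0, 1], half the vector value
    for a binary problem).
    """
    onehot = np.eye(2)[preds.true_label]
    if variant == "vector":
        return float(np.mean(np.sum((preds.probs - onehot) ** 2, axis=1)))
    if variant == "positive":
        return float(np.mean((preds.probs[:, 1] - preds.true_label) ** 2))
    raise ValueError(f"unknown Brier variant {variant!r}")


def confusion_counts(preds: PredictionSet) -> ConfusionCounts:
    y, yhat = preds.true_label, preds.pred_label
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def classification_summary(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy)."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive-class samples: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative-class samples: specificity undefined")
    sen = counts.tp / (counts.tp + counts.fn)
    spe = counts.tn / (counts.tn + counts.fp)
    return sen, spe, (sen + spe) / 2.0


def mcnemar_test(preds_a: PredictionSet, preds_b: PredictionSet,
                 alpha: float = 0.05, exact_threshold: int = 25):
    """McNemar's paired test on two classifiers over the same samples.

    Uses the exact binomial test on the discordant pairs when there are
    fewer than ``exact_threshold`` of them, and the chi-square test with
    continuity correction otherwise.

    Returns (statistic, p_value, significant) where ``significant`` is
    ``p < alpha``. With no discordant pairs the classifiers are
    indistinguishable and p = 1.
    """
    if len(preds_a) != len(preds_b) or np.any(preds_a.true_label != preds_b.true_label):
        raise ValueError("prediction sets must cover the same samples and labels")
    ca, cb = preds_a.correct, preds_b.correct
    b = int(np.sum(ca & ~cb))  # a right, b wrong
    c = int(np.sum(~ca & cb))  # a wrong, b right
    if b + c == 0:
        return 0.0, 1.0, False
    table = np.array([[int(np.sum(ca & cb)), b], [c, int(np.sum(~ca & ~cb))]])
    res = _sm_mcnemar(table, exact=(b + c < exact_threshold), correction=True)
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), p, p < alpha


def metric_suite(preds: PredictionSet, n_bins: int = DEFAULT_BINS) -> dict[str, float]:
    """The full calibration metric set on one prediction set."""
    profile = reliability_profile(preds, bin_predictions(preds, n_bins, "equal_width"))
    sen, spe, bacc = classification_summary(confusion_counts(preds))
    return {
        "ECE": ece(profile),
        "AECE": adaptive_ece(preds, min(n_bins, len(preds))),
        "OE": overconfidence_error(profile),
        "MCE": mce(profile),
        "BS": brier_score(preds),
        "SEN": sen,
        "SPE": spe,
        "BACC": bacc,
    }


# -- report writers ----------------------------------------------------------

def write_metrics_csv(path, rows: dict[str, dict[str, float]]) -> None:
    """One row per (model, metric): ``model,metric,value``."""
    with open(path, "w") as fh:
        fh.write("model,metric,value\n")
        for model, metrics in rows.items():
            for metric, value in metrics.items():
                fh.write(f"{model},{metric},{value:.10g}\n")


def reliability_to_json(profile: ReliabilityProfile, n_bins_edges: bool = True) -> str:
    """Serialise a reliability profile (the data behind a diagram)."""
    m = profile.n_bins
    payload = {
        "scheme": profile.scheme,
        "n_bins": m,
        "n": profile.n,
        "counts": profile.counts.tolist(),
        "accuracy": [None if not ok else a for ok, a in zip(profile.nonempty, profile.accuracy)],
        "mean_confidence": [None if not ok else c
                            for ok, c in zip(profile.nonempty, profile.mean_confidence)],
    }
    if profile.scheme == "equal_width" and n_bins_edges:
        payload["bin_edges"] = np.linspace(0.0, 1.0, m + 1).tolist()
    return json.dumps(payload, indent=2)


def reliability_to_table(profile: ReliabilityProfile) -> str:
    """Plain-text table mirroring :func:`reliability_to_json`."""
    lines = ["bin\tcount\taccuracy\tmean_confidence"]
    for i in range(profile.n_bins):
        if profile.counts[i]:
            lines.append(f"{i + 1}\t{profile.counts[i]}\t"
                         f"{profile.accuracy[i]:.6f}\t{profile.mean_confidence[i]:.6f}")
        else:
            lines.append(f"{i + 1}\t0\tNA\tNA")
    return "\n".join(lines)
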