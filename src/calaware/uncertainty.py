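"""Epistemic and aleatoric uncertainty estimation for the VAE classifier.

Both estimators propagate K stochastic variants of each subject through
the classifier and summarise the K binary predictions:

* epistemic — resample the VAE latent space: the first pass uses the
  latent mean (the "original embedding"), the remaining K−1 use
  reparameterised draws from the per-frame posterior.
* aleatoric — perturb the input segmentation itself: labels of pixels
  within a 1-pixel band of each class boundary are resampled (to a random
  4-neighbour's label) with a fixed rate, emulating the frame-to-frame
  variability a stochastic segmentation model produces, and each perturbed
  stack is propagated through VAE and classifier.

The sampled confidence C_i is the positive fraction of the K predictions;
the calibration metric suite is then evaluated with confidence
max(C, 1−C) and the majority-vote prediction, giving the per-source
(epistemic vs aleatoric) calibration summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import calibration as calib
from .calibration import PredictionSet, ReliabilityProfile
from .model import CineVAEClassifier, component_seed

__all__ = ["SampledPredictions", "epistemic_samples", "aleatoric_samples",
           "perturb_stack", "perturb_stacks", "sampled_confidence", "disagreement_rate",
           "metrics_under_uncertainty", "uncertainty_report_rows", "write_uncertainty_csv"]

DEFAULT_K = 20
DEFAULT_PERTURBATION_RATE = 0.2


@dataclass(frozen=True)
class SampledPredictions:
    """K binary predictions per subject from repeated stochastic passes."""

    preds: np.ndarray  # (n_subjects, K) in {0, 1}
    source: Literal["epistemic", "aleatoric"]

    def __post_init__(self):
        p = np.asarray(self.preds, dtype=int)
        if p.ndim != 2 or p.shape[1] < 2:
            raise ValueError("need a (n_subjects, K>=2) prediction array")
        if not np.all(np.isin(p, [0, 1])):
            raise ValueError("sampled predictions must be 0/1")
        object.__setattr__(self, "preds", p)

    @property
    def n_samples(self) -> int:
        return self.preds.shape[1]


def _check_fitted(model: CineVAEClassifier) -> None:
    if not hasattr(model, "params_"):
        raise ValueError("model is not fitted")


def epistemic_samples(model: CineVAEClassifier, X, n_samples: int = DEFAULT_K,
                      seed: int = 0) -> SampledPredictions:
    """Latent-space resampling: K classifier passes per subject."""
    _check_fitted(model)
    return SampledPredictions(model.epistemic_draws(X, n_samples, seed), "epistemic")


def _neighbours(frames: np.ndarray) -> np.ndarray:
    """4-neighbour labels with edge replication: (..., H, W) -> (4, ..., H, W)."""
    up = np.concatenate([frames[..., :1, :], frames[..., :-1, :]], axis=-2)
    down = np.concatenate([frames[..., 1:, :], frames[..., -1:, :]], axis=-2)
    left = np.concatenate([frames[..., :, :1], frames[..., :, :-1]], axis=-1)
    right = np.concatenate([frames[..., :, 1:], frames[..., :, -1:]], axis=-1)
    return np.stack([up, down, left, right])


def perturb_stacks(X: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Resample boundary-band pixel labels with probability ``rate``.

    A pixel is in the band when any 4-neighbour carries a different label; a
    resampled pixel takes the label of a uniformly chosen 4-neighbour.
    Frames are perturbed independently (segmentation noise is per-frame).
    Works on any (..., H, W) stack of label maps.
    """
    nb = _neighbours(X)
    band = (nb != X).any(axis=0)
    hit = band & (rng.random(X.shape) < rate)
    choice = rng.integers(0, 4, X.shape)
    resampled = np.take_along_axis(nb, choice[None], axis=0)[0]
    return np.where(hit, resampled, X)


def perturb_stack(stack: np.ndarray, rate: float, rng: np.random.Generator,
                  n_classes: int = 3) -> np.ndarray:
    """Single-subject convenience wrapper around :func:`perturb_stacks`."""
    return perturb_stacks(np.asarray(stack), rate, rng)


def aleatoric_samples(model: CineVAEClassifier, X, n_samples: int = DEFAULT_K,
                      perturbation_rate: float = DEFAULT_PERTURBATION_RATE,
                      seed: int = 0) -> SampledPredictions:
    """Input-perturbation sampling: the original stack plus K−1 perturbed
    stacks propagated through VAE and classifier."""
    _check_fitted(model)
    if not (0 < perturbation_rate < 1):
        raise ValueError("perturbation_rate must be in (0, 1)")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = np.asarray(X)
    rng = np.random.default_rng(component_seed(seed, "aleatoric"))
    n = X.shape[0]
    preds = np.empty((n, n_samples), dtype=int)
    preds[:, 0] = model.predict(X)
    for j in range(1, n_samples):
        perturbed = perturb_stacks(X, perturbation_rate, rng)
        if not np.any(perturbed):
            raise ValueError("perturbation destroyed all foreground labels")
        preds[:, j] = model.predict(perturbed)
    return SampledPredictions(preds, "aleatoric")


def sampled_confidence(samples: SampledPredictions) -> np.ndarray:
    """C_i: proportion of positive predictions among the K samples."""
    return samples.preds.mean(axis=1)


def disagreement_rate(samples: SampledPredictions) -> float:
    """Fraction of subjects whose K predictions are not unanimous."""
    c = sampled_confidence(samples)
    return float(np.mean((c > 0) & (c < 1)))


def _profile_from(confidence: np.ndarray, correct: np.ndarray,
                  n_bins: int, scheme: str) -> ReliabilityProfile:
    confidence = np.where(confidence == 0.5, 0.5 + 1e-12, confidence)
    ps = PredictionSet.from_positive_probs(confidence, correct.astype(int))
    # confidence > 0.5 always here, so predicted class is 1 and `correct`
    # doubles as the accuracy indicator through the label slot
    partition = calib.bin_predictions(ps, n_bins, scheme)
    return calib.reliability_profile(ps, partition)


def metrics_under_uncertainty(samples: SampledPredictions, labels,
                              n_bins: int = 15,
                              accuracy_from: Literal["majority", "original"] = "majority",
                              ) -> dict[str, float]:
    """Calibration metric suite on the sampled predictions.

    The per-subject confidence is max(C, 1−C); the predicted class is the
    majority vote (ties predict positive) or, optionally, the single
    original prediction (the first sample). Returns ECE/AECE/OE/MCE/BS.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.shape[0] != samples.preds.shape[0]:
        raise ValueError("labels do not match the sampled predictions")
    c = sampled_confidence(samples)
    # exact tie C=0.5: majority vote predicts positive (fixed convention);
    # the infinitesimal nudge keeps the argmax consistent without moving
    # any metric by more than 1e-12
    c_adj = np.where(c == 0.5, 0.5 + 1e-12, c)
    preds = PredictionSet.from_positive_probs(c_adj, labels)
    if accuracy_from == "majority":
        eval_preds = preds
        correct = preds.correct
        confidence = preds.confidence
    elif accuracy_from == "original":
        original = samples.preds[:, 0]
        correct = original == labels
        confidence = preds.confidence
        eval_preds = None
    else:
        raise ValueError(f"unknown accuracy_from {accuracy_from!r}")

    if eval_preds is not None:
        profile = calib.reliability_profile(
            eval_preds, calib.bin_predictions(eval_preds, n_bins, "equal_width"))
        aece = calib.adaptive_ece(eval_preds, min(n_bins, len(eval_preds)))
        bs = calib.brier_score(eval_preds)
    else:
        profile = _profile_from(confidence, correct, n_bins, "equal_width")
        adaptive = _profile_from(confidence, correct,
                                 min(n_bins, confidence.size), "adaptive")
        aece = calib.ece(adaptive)
        onehot = np.eye(2)[labels]
        probs = np.column_stack([1.0 - c, c])
        bs = float(np.mean(np.sum((probs - onehot) ** 2, axis=1)))
    return {
        "ECE": calib.ece(profile),
        "AECE": aece,
        "OE": calib.overconfidence_error(profile),
        "MCE": calib.mce(profile),
        "BS": bs,
    }


def write_uncertainty_csv(path, samples: SampledPredictions, labels) -> None:
    """Per-subject report: sampled confidence, majority vote, label, source."""
    rows = uncertainty_report_rows(samples, labels)
    with open(path, "w") as fh:
        fh.write("subject,sampled_confidence,majority_vote,label,source\n")
        for r in rows:
            fh.write(f"{r['subject']},{r['sampled_confidence']:.6g},"
                     f"{r['majority_vote']},{r['label']},{r['source']}\n")


def uncertainty_report_rows(samples: SampledPredictions, labels) -> list[dict]:
    """Per-subject CSV-ready rows: sampled confidence, majority vote, source."""
    c = sampled_confidence(samples)
    majority = (c >= 0.5).astype(int)
    labels = np.asarray(labels, dtype=int).ravel()
    return [
        {"subject": i, "sampled_confidence": float(c[i]), "majority_vote": int(majority[i]),
         "label": int(labels[i]), "source": samples.source}
        for i in range(c.size)
    ]
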