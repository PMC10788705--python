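"""Per-frame VAE over cine segmentation label maps with a latent-space classifier.

The backbone mirrors the architecture the uncertainty-aware strategies plug
into: each cardiac frame's label map is encoded by a shared variational
encoder into a Gaussian latent code, a decoder reconstructs the (coarsened)
segmentation frame-by-frame, and a small classifier predicts the binary
outcome from the concatenated per-frame latent codes. The composite
training objective is

    L = L_RE + λ_KL · L_KL + λ_C · L_C (+ λ_N · L_N)

with the strategy term L_N (or the Confidence Weight reweighting of L_C)
supplied by :mod:`calaware.losses`.

The encoder/decoder are multilayer perceptrons over block-pooled one-hot
label maps (pool factor 4 by default): pooling keeps the desk-scale
protocol fast on one CPU, and flips/right-angle rotations commute with
block pooling so augmentation remains exact. Everything is expressed as a
scikit-learn estimator, :class:`CineVAEClassifier`.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import calibration as calib
from ._autodiff import Tensor, log_softmax
from .losses import (LossHyperparams, TrainingBatch, composite_loss,
                     confidence_weights, strategy_loss, weighted_classifier_loss)

__all__ = ["CineVAEClassifier", "SelectionRecord", "kl_divergence",
           "component_seed", "save_checkpoint", "load_checkpoint"]


def component_seed(base_seed: int, label: str) -> int:
    """Stable per-component seed derived from a run seed and a label."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def kl_divergence(mean: np.ndarray, log_var: np.ndarray) -> float:
    """Closed-form KL(N(μ, σ²) ‖ N(0, I)), summed over latent dimensions and
    averaged over leading axes: mean of ½ Σ_d (μ² + σ² − 1 − log σ²)."""
    mean = np.asarray(mean, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    per = 0.5 * np.sum(mean**2 + np.exp(log_var) - 1.0 - log_var, axis=-1)
    return float(np.mean(per))


@dataclass
class SelectionRecord:
    """Per-epoch validation metrics plus the parameters that produced them."""

    epoch: int
    val_bacc: float
    val_ece: float
    checkpoint: dict[str, np.ndarray] = field(repr=False)


_DIHEDRAL = [(k, flip) for k in range(4) for flip in (False, True)]


class CineVAEClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier over cine segmentation stacks via a per-frame VAE.

    Parameters
    ----------
    latent_dim : width d of each frame's Gaussian latent code.
    hidden : encoder/decoder hidden width.
    classifier_hidden : classifier hidden width (default 32).
    pool : block-pooling factor applied to the one-hot label maps.
    n_classes : number of segmentation labels (background, blood pool,
        myocardium by default).
    strategy : one of ``calaware.losses.STRATEGIES``.
    hyperparams : a :class:`LossHyperparams`; defaults to the desk preset
        for the chosen strategy.
    epochs, batch_size : training schedule (batch size 8 by default).
    lr_vae, lr_clf : Adam learning rates for the VAE and classifier
        parameter groups (a single shared rate when equal).
    validation_fraction : held-out fraction used for the per-epoch
        selection records when no explicit validation set is passed to
        ``fit``.
    augment : random flips and right-angle rotations, applied consistently
        across a subject's frames.
    n_confidence_samples : latent draws per sample for the Confidence
        Weight strategy (K = 20).
    keep_checkpoints : store a parameter snapshot in every
        :class:`SelectionRecord` (needed for post-hoc model selection).
    random_state : seed governing initialisation, shuffling, augmentation
        and latent sampling.
    """

    def __init__(self, latent_dim: int = 64, hidden: int = 64, classifier_hidden: int = 32,
                 pool: int = 4, n_classes: int = 3, strategy: str = "baseline",
                 hyperparams: LossHyperparams | None = None, epochs: int = 30,
                 batch_size: int = 8, lr_vae: float = 1e-3, lr_clf: float = 3e-3,
                 validation_fraction: float = 0.15, augment: bool = True,
                 n_confidence_samples: int = 20, n_bins_eval: int = 15,
                 keep_checkpoints: bool = True, random_state: int = 0):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.classifier_hidden = classifier_hidden
        self.pool = pool
        self.n_classes = n_classes
        self.strategy = strategy
        self.hyperparams = hyperparams
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_vae = lr_vae
        self.lr_clf = lr_clf
        self.validation_fraction = validation_fraction
        self.augment = augment
        self.n_confidence_samples = n_confidence_samples
        self.n_bins_eval = n_bins_eval
        self.keep_checkpoints = keep_checkpoints
        self.random_state = random_state

    # -- input handling -------------------------------------------------------

    def _validate_stack(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4:
            raise ValueError(f"expected (n_subjects, frames, height, width), got {X.shape}")
        if hasattr(self, "input_shape_") and X.shape[1:] != self.input_shape_:
            raise ValueError(f"stack shape {X.shape[1:]} does not match fitted {self.input_shape_}")
        if X.shape[2] % self.pool or X.shape[3] % self.pool:
            raise ValueError(f"spatial size {X.shape[2:]} not divisible by pool={self.pool}")
        if X.min() < 0 or X.max() >= self.n_classes:
            raise ValueError(f"label values outside [0, {self.n_classes - 1}]")
        return X

    def _pooled(self, X: np.ndarray) -> np.ndarray:
        """One-hot encode and block-pool: (n, T, H, W) -> (n, T, Hp, Wp, C)."""
        n, t, h, w = X.shape
        p = self.pool
        out = np.empty((n, t, h // p, w // p, self.n_classes), dtype=np.float32)
        for c in range(self.n_classes):
            m = (X == c).astype(np.float32)
            out[..., c] = m.reshape(n, t, h // p, p, w // p, p).mean(axis=(3, 5))
        return out

    # -- parameters -----------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        g = self._grid_dim
        d, hid, ch = self.latent_dim, self.hidden, self.classifier_hidden
        t = self.n_frames_

        def glorot(shape):
            scale = np.sqrt(2.0 / sum(shape))
            return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        return {
            "enc_w1": glorot((g, hid)), "enc_b1": zeros(hid),
            "enc_wm": glorot((hid, d)), "enc_bm": zeros(d),
            "enc_wv": glorot((hid, d)), "enc_bv": zeros(d),
            "dec_w1": glorot((d, hid)), "dec_b1": zeros(hid),
            "dec_w2": glorot((hid, g)), "dec_b2": zeros(g),
            "clf_w1": glorot((t * d, ch)), "clf_b1": zeros(ch),
            "clf_w2": glorot((ch, 2)), "clf_b2": zeros(2),
        }

    @property
    def _grid_dim(self) -> int:
        hp, wp = self.input_shape_[1] // self.pool, self.input_shape_[2] // self.pool
        return hp * wp * self.n_classes

    def _eval_params(self) -> dict[str, Tensor]:
        return {k: Tensor(v.data) for k, v in self.params_.items()}

    def get_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params_.items()}

    def set_parameters(self, checkpoint: dict[str, np.ndarray]) -> "CineVAEClassifier":
        for k, v in self.params_.items():
            v.data = np.array(checkpoint[k], dtype=v.data.dtype)
        return self

    # -- forward passes -------------------------------------------------------

    @staticmethod
    def _encode_t(p: dict[str, Tensor], x2d: Tensor) -> tuple[Tensor, Tensor]:
        h = (x2d @ p["enc_w1"] + p["enc_b1"]).tanh()
        return h @ p["enc_wm"] + p["enc_bm"], h @ p["enc_wv"] + p["enc_bv"]

    def _decode_t(self, p: dict[str, Tensor], z: Tensor) -> Tensor:
        h = (z @ p["dec_w1"] + p["dec_b1"]).tanh()
        logits = h @ p["dec_w2"] + p["dec_b2"]
        cells = self._grid_dim // self.n_classes
        return log_softmax(logits.reshape(z.shape[0], cells, self.n_classes), axis=2)

    @staticmethod
    def _classify_t(p: dict[str, Tensor], zcat: Tensor) -> Tensor:
        h = (zcat @ p["clf_w1"] + p["clf_b1"]).tanh()
        return h @ p["clf_w2"] + p["clf_b2"]

    def _frames2d(self, pooled: np.ndarray) -> np.ndarray:
        n, t = pooled.shape[:2]
        return pooled.reshape(n * t, -1)

    # -- public operations ----------------------------------------------------

    def encode(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame latent means and log-variances, shape (n, T, d)."""
        X = self._validate_stack(X)
        p = self._eval_params()
        mu, lv = self._encode_t(p, Tensor(self._frames2d(self._pooled(X)).astype(float)))
        n, t = X.shape[:2]
        return (mu.data.reshape(n, t, self.latent_dim),
                lv.data.reshape(n, t, self.latent_dim))

    def decode(self, z: np.ndarray, upsample: bool = False) -> np.ndarray:
        """Per-frame class-probability maps from latent codes (…, d).

        Returns maps on the model's working grid (H/pool, W/pool, classes),
        nearest-neighbour upsampled to the input resolution on request.
        Each pixel's distribution sums to 1.
        """
        z = np.asarray(z, dtype=float)
        if z.shape[-1] != self.latent_dim:
            raise ValueError(f"latent dimension {z.shape[-1]} != {self.latent_dim}")
        lead = z.shape[:-1]
        logp = self._decode_t(self._eval_params(), Tensor(z.reshape(-1, self.latent_dim)))
        hp, wp = self.input_shape_[1] // self.pool, self.input_shape_[2] // self.pool
        maps = np.exp(logp.data).reshape(*lead, hp, wp, self.n_classes)
        if upsample:
            maps = maps.repeat(self.pool, axis=-3).repeat(self.pool, axis=-2)
        return maps

    def classify_latent(self, z: np.ndarray) -> np.ndarray:
        """Class probabilities from per-frame latent codes (n, T, d)."""
        z = np.asarray(z, dtype=float)
        if z.ndim != 3 or z.shape[1] != self.n_frames_ or z.shape[2] != self.latent_dim:
            raise ValueError(f"expected latent codes (n, {self.n_frames_}, {self.latent_dim})")
        logits = self._classify_t(self._eval_params(), Tensor(z.reshape(z.shape[0], -1)))
        return np.exp(log_softmax(logits, axis=1).data)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities using the per-frame latent means."""
        mu, _ = self.encode(X)
        return self.classify_latent(mu)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return (proba[:, 1] > proba[:, 0]).astype(int)

    def prediction_set(self, X, y) -> calib.PredictionSet:
        return calib.PredictionSet(self.predict_proba(X), y)

    # -- training -------------------------------------------------------------

    def _resolve_hp(self) -> LossHyperparams:
        if self.hyperparams is not None:
            return self.hyperparams
        return LossHyperparams.preset(self.strategy, task="desk")

    def _augment(self, xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = xb.copy()
        for i in range(xb.shape[0]):
            k, flip = _DIHEDRAL[rng.integers(len(_DIHEDRAL))]
            s = np.rot90(out[i], k=k, axes=(1, 2))
            if flip:
                s = s[:, :, ::-1]
            out[i] = s
        return out

    def _sampled_confidence_np(self, mu: np.ndarray, lv: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
        """C_i: positive fraction over K latent draws (first draw = mean).

        Used by the Confidence Weight strategy; runs outside the autodiff
        graph, so the weights are constants with respect to gradients.
        """
        k = self.n_confidence_samples
        n = mu.shape[0]
        p = self._eval_params()
        pos = np.zeros(n)
        sd = np.exp(0.5 * lv)
        for j in range(k):
            z = mu if j == 0 else mu + sd * rng.standard_normal(mu.shape)
            logits = self._classify_t(p, Tensor(z.reshape(n, -1))).data
            pos += logits[:, 1] > logits[:, 0]
        return pos / k

    def _avu_threshold_update(self, pooled: np.ndarray, y: np.ndarray) -> float:
        """Mean predictive entropy of correctly classified training samples."""
        mu, _ = self._encode_np(pooled)
        proba = self.classify_latent(mu)
        pred = (proba[:, 1] > proba[:, 0]).astype(int)
        correct = pred == y
        if not correct.any():
            return 1.0
        pc = np.clip(proba[correct], 1e-12, 1.0)
        return float(np.mean(-(pc * np.log(pc)).sum(axis=1)))

    def _encode_np(self, pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self._eval_params()
        mu, lv = self._encode_t(p, Tensor(self._frames2d(pooled).astype(float)))
        n, t = pooled.shape[:2]
        return (mu.data.reshape(n, t, self.latent_dim), lv.data.reshape(n, t, self.latent_dim))

    def fit(self, X, y=None, X_val=None, y_val=None, vae_init: dict | None = None,
            pretrain_only: bool = False):
        """Train the VAE (+ classifier) with the configured strategy.

        When ``y`` is None, or ``pretrain_only`` is set, only the VAE terms
        are optimised (reconstruction + KL) — this produces the shared
        pre-trained VAE state the strategies start from. Otherwise the full
        composite objective is optimised and per-epoch validation BACC/ECE
        are recorded in ``records_``.
        """
        X = np.asarray(X)
        self.input_shape_ = X.shape[1:]
        self.n_frames_ = X.shape[1]
        X = self._validate_stack(X)
        pretrain = pretrain_only or y is None
        if not pretrain:
            y = np.asarray(y, dtype=int).ravel()
            if not np.all(np.isin(y, [0, 1])):
                raise ValueError("outcome labels must be 0/1")
            self.classes_ = np.array([0, 1])

        ss = np.random.SeedSequence(component_seed(self.random_state, "fit"))
        rng_init, rng_shuffle, rng_aug, rng_latent, rng_cw, rng_split = (
            np.random.default_rng(s) for s in ss.spawn(6))

        self.params_ = self._init_params(rng_init)
        if vae_init is not None:
            for k in self.params_:
                if k in vae_init and not k.startswith("clf_"):
                    self.params_[k].data = np.array(vae_init[k], dtype=float)

        hp = self._resolve_hp()
        # held-out validation split (stratified) when none is supplied
        if not pretrain and X_val is None and self.validation_fraction > 0:
            idx = np.arange(len(X))
            val_idx = []
            for cls in (0, 1):
                c_idx = idx[y == cls]
                rng_split.shuffle(c_idx)
                n_val = max(1, int(round(self.validation_fraction * c_idx.size)))
                val_idx.append(c_idx[:n_val])
            val_idx = np.concatenate(val_idx)
            train_mask = np.ones(len(X), bool)
            train_mask[val_idx] = False
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[train_mask], y[train_mask]

        pooled = self._pooled(X)
        pooled_val = self._pooled(self._validate_stack(X_val)) if X_val is not None else None

        adam_m = {k: np.zeros_like(v.data) for k, v in self.params_.items()}
        adam_v = {k: np.zeros_like(v.data) for k, v in self.params_.items()}
        adam_t = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        n = pooled.shape[0]
        t_frames = self.n_frames_
        self.records_: list[SelectionRecord] = []
        self.loss_history_: list[dict[str, float]] = []
        avu_threshold = hp.avu_threshold

        for epoch in range(self.epochs):
            if (not pretrain and self.strategy == "avuc" and epoch >= 3):
                avu_threshold = self._avu_threshold_update(pooled, y)
            order = rng_shuffle.permutation(n)
            epoch_terms: dict[str, float] = {"loss": 0.0, "re": 0.0, "kl": 0.0, "ce": 0.0}
            n_steps = 0
            for start in range(0, n, self.batch_size):
                bidx = order[start:start + self.batch_size]
                xb = pooled[bidx]
                if self.augment:
                    xb = self._augment(xb, rng_aug)
                b = bidx.size
                x2d = Tensor(self._frames2d(xb).astype(float))
                mu, lv = self._encode_t(self.params_, x2d)
                noise = rng_latent.standard_normal(mu.shape)
                z = mu + (lv * 0.5).exp() * Tensor(noise)
                logp_maps = self._decode_t(self.params_, z)
                q = x2d.data.reshape(logp_maps.shape)
                l_re = -(Tensor(q) * logp_maps).sum(axis=2).mean()
                l_kl = (0.5 * (mu**2 + lv.exp() - 1.0 - lv).sum(axis=1)).mean()

                if pretrain:
                    total = composite_loss(l_re, l_kl, 0.0, hp)
                    epoch_terms["ce"] += 0.0
                else:
                    yb = y[bidx]
                    zcat = mu.reshape(b, t_frames * self.latent_dim)
                    logits = self._classify_t(self.params_, zcat)
                    batch = TrainingBatch.from_logits(logits, yb)
                    if self.strategy == "confidence_weight":
                        c_i = self._sampled_confidence_np(
                            mu.data.reshape(b, t_frames, -1),
                            lv.data.reshape(b, t_frames, -1), rng_cw)
                        weights = confidence_weights(c_i, yb, hp.w)
                        l_c = weighted_classifier_loss(batch, weights)
                        extra = None
                    else:
                        l_c = batch.cross_entropy()
                        if self.strategy == "avuc":
                            extra = strategy_loss(
                                "avuc", batch,
                                LossHyperparams(avu_threshold=avu_threshold))
                        else:
                            extra = strategy_loss(self.strategy, batch, hp)
                    total = composite_loss(l_re, l_kl, l_c, hp, extra)
                    epoch_terms["ce"] += float(l_c.data)

                total.backward()
                adam_t += 1
                for k, param in self.params_.items():
                    if param.grad is None:
                        continue
                    lr = self.lr_clf if k.startswith("clf_") else self.lr_vae
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * param.grad
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * param.grad**2
                    m_hat = adam_m[k] / (1 - beta1**adam_t)
                    v_hat = adam_v[k] / (1 - beta2**adam_t)
                    param.data = param.data - lr * m_hat / (np.sqrt(v_hat) + eps)
                    param.grad = None
                epoch_terms["loss"] += float(total.data)
                epoch_terms["re"] += float(l_re.data)
                epoch_terms["kl"] += float(l_kl.data)
                n_steps += 1

            self.loss_history_.append({k: v / n_steps for k, v in epoch_terms.items()})

            if not pretrain and pooled_val is not None:
                mu_val, _ = self._encode_np(pooled_val)
                proba = self.classify_latent(mu_val)
                preds = calib.PredictionSet(proba, np.asarray(y_val, dtype=int))
                _, _, bacc = calib.classification_summary(calib.confusion_counts(preds))
                profile = calib.reliability_profile(
                    preds, calib.bin_predictions(preds, self.n_bins_eval, "equal_width"))
                self.records_.append(SelectionRecord(
                    epoch=epoch, val_bacc=bacc, val_ece=calib.ece(profile),
                    checkpoint=self.get_parameters() if self.keep_checkpoints else {}))
        return self

    def epistemic_draws(self, X, n_samples: int, seed: int) -> np.ndarray:
        """(n, K) binary predictions: first from the latent means, the rest
        from reparameterised latent draws."""
        if n_samples < 2:
            raise ValueError("need at least 2 samples")
        mu, lv = self.encode(X)
        rng = np.random.default_rng(seed)
        n = mu.shape[0]
        preds = np.empty((n, n_samples), dtype=int)
        sd = np.exp(0.5 * lv)
        for j in range(n_samples):
            z = mu if j == 0 else mu + sd * rng.standard_normal(mu.shape)
            proba = self.classify_latent(z)
            preds[:, j] = (proba[:, 1] > proba[:, 0]).astype(int)
        return preds


def save_checkpoint(path, model: CineVAEClassifier) -> None:
    """Parameters + estimator config + seed, as a single .npz archive."""
    meta = {"config": model.get_params(), "seed": model.random_state,
            "input_shape": list(getattr(model, "input_shape_", ()))}
    hp = meta["config"].pop("hyperparams")
    if hp is not None:
        meta["config"]["hyperparams"] = vars(hp)
    np.savez(path, __meta__=json.dumps(meta), **model.get_parameters())


def load_checkpoint(path) -> CineVAEClassifier:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = meta["config"]
    if cfg.get("hyperparams") is not None:
        cfg["hyperparams"] = LossHyperparams(**cfg["hyperparams"])
    model = CineVAEClassifier(**cfg)
    model.input_shape_ = tuple(meta["input_shape"])
    model.n_frames_ = model.input_shape_[0]
    model.classes_ = np.array([0, 1])
    model.params_ = model._init_params(np.random.default_rng(0))
    model.set_parameters(params)
    return model
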