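"""Synthetic cine segmentation phantoms with a binary outcome.

Each subject is a short movie of label maps showing a contracting ring
("myocardium", label 2) around a disk ("blood pool", label 1) on background
(label 0) — the geometry a cardiac short-axis segmentation stack presents
to the VAE. The outer radius follows a smooth contraction curve over the
cardiac cycle; subjects of outcome class 1 contract by ``base_contraction +
effect_size`` and class 0 by ``base_contraction``, both jittered per
subject by ``noise_sd``. Difficulty is therefore tunable along two axes:

* epistemic — class overlap, via ``effect_size`` vs ``noise_sd`` and the
  number of subjects;
* aleatoric — outcome-label noise, via ``label_flip_rate`` (labels are
  flipped with this probability after the geometry is drawn).

Generation is a pure function of the config, so every experiment is
reproducible without any stored data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SyntheticConfig", "SubjectSample", "SyntheticDataset", "generate_dataset",
           "split", "desk_config", "paper_scale_config", "save_dataset", "load_dataset",
           "export_nifti", "load_nifti_stack"]

LABELS = (0, 1, 2)  # background, blood pool, myocardium


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the desk-scale benchmark conditions."""

    n_subjects: int = 600
    frames: int = 8
    image_size: tuple[int, int] = (64, 64)
    prevalence: float = 0.4
    effect_size: float = 0.1
    base_contraction: float = 0.15
    noise_sd: float = 0.06
    label_flip_rate: float = 0.0
    outer_radius_frac: float = 0.36
    ring_frac: float = 0.3
    center_jitter: float = 2.0
    radius_jitter_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.image_size, int):
            object.__setattr__(self, "image_size", (self.image_size, self.image_size))
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if not (0 <= self.label_flip_rate < 0.5):
            raise ValueError("label_flip_rate must be in [0, 0.5)")
        if self.frames < 1 or self.n_subjects < 1:
            raise ValueError("need at least one frame and one subject")
        h, w = self.image_size
        r_max = self.outer_radius_frac * min(h, w) * (1 + self.radius_jitter_frac)
        if r_max + self.center_jitter > min(h, w) / 2 - 1:
            raise ValueError("ring geometry exceeds image bounds")


@dataclass(frozen=True)
class SubjectSample:
    """One training unit: a T-frame label-map stack plus the binary outcome."""

    seg_stack: np.ndarray
    outcome: int

    def __post_init__(self):
        if self.seg_stack.ndim != 3:
            raise ValueError("seg_stack must be (frames, height, width)")
        if not np.all(np.isin(self.seg_stack, LABELS)):
            raise ValueError(f"label values outside {LABELS}")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0/1")


@dataclass
class SyntheticDataset:
    X: np.ndarray          # (n, T, H, W) uint8 label maps
    y: np.ndarray          # (n,) observed binary outcomes
    truth: dict            # latent generation parameters, for recovery tests
    config: SyntheticConfig

    def __len__(self) -> int:
        return self.X.shape[0]

    def subjects(self):
        for i in range(len(self)):
            yield SubjectSample(self.X[i], int(self.y[i]))


def desk_config(**overrides) -> SyntheticConfig:
    """Desk-scale preset: 600 subjects, 8 frames, 64×64."""
    return SyntheticConfig(**overrides)


def paper_scale_config(**overrides) -> SyntheticConfig:
    """Format-faithful preset: 80×80 pixels, T=25 frames."""
    defaults = dict(frames=25, image_size=(80, 80))
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _contraction_curve(frames: int) -> np.ndarray:
    """Smooth 0→1→0 contraction over the cycle (end-diastole at frame 0)."""
    t = np.arange(frames)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / frames))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw a full dataset; bit-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    n, t = cfg.n_subjects, cfg.frames
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    y_true = (rng.random(n) < cfg.prevalence).astype(int)
    amplitude = (cfg.base_contraction + cfg.effect_size * y_true
                 + rng.normal(0.0, cfg.noise_sd, n))
    amplitude = np.clip(amplitude, 0.0, 0.85)
    centers = (np.array([[h / 2, w / 2]]) + rng.uniform(-cfg.center_jitter,
                                                        cfg.center_jitter, (n, 2)))
    r0 = cfg.outer_radius_frac * min(h, w) * (
        1.0 + rng.uniform(-cfg.radius_jitter_frac, cfg.radius_jitter_frac, n))
    curve = _contraction_curve(t)

    X = np.zeros((n, t, h, w), dtype=np.uint8)
    for i in range(n):
        dist = np.hypot(yy - centers[i, 0], xx - centers[i, 1])
        for k in range(t):
            scale = 1.0 - amplitude[i] * curve[k]
            r_out = r0[i] * scale
            thickness = max(cfg.ring_frac * r_out, 2.0)
            r_in = max(r_out - thickness, 1.5)
            frame = X[i, k]
            frame[dist < r_out] = 2
            frame[dist < r_in] = 1

    flips = rng.random(n) < cfg.label_flip_rate
    y_obs = np.where(flips, 1 - y_true, y_true)

    truth = {"y_true": y_true, "amplitude": amplitude, "outer_radius": r0,
             "centers": centers, "flipped": flips}
    return SyntheticDataset(X=X, y=y_obs, truth=truth, config=cfg)


def split(dataset: SyntheticDataset | tuple, fractions=(0.72, 0.08, 0.20),
          seed: int = 0) -> dict[str, np.ndarray]:
    """Label-stratified train/validation/test index partition.

    Per outcome class, subjects are shuffled and allocated to splits by the
    largest-remainder rule on ``n_class · fraction``, so splits are
    disjoint, exhaustive, and each split's prevalence is within one subject
    of the global prevalence.
    """
    y = dataset.y if isinstance(dataset, SyntheticDataset) else np.asarray(dataset[1])
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0, atol=1e-9):
        raise ValueError("fractions must sum to 1")
    names = ("train", "val", "test")[:len(fractions)]
    rng = np.random.default_rng(seed)
    parts: dict[str, list] = {name: [] for name in names}
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        quota_f = idx.size * fractions
        quota = np.floor(quota_f).astype(int)
        rem = idx.size - quota.sum()
        # distribute the remainder to the largest fractional parts
        order = np.argsort(-(quota_f - quota), kind="stable")
        quota[order[:rem]] += 1
        offsets = np.concatenate([[0], np.cumsum(quota)])
        for name, lo, hi in zip(names, offsets[:-1], offsets[1:]):
            parts[name].append(idx[lo:hi])
    out = {name: np.sort(np.concatenate(chunks)) for name, chunks in parts.items()}
    for name, idx in out.items():
        for cls in np.unique(y):
            if not np.any(y[idx] == cls):
                raise ValueError(f"split {name!r} received no subjects of class {cls}")
    return out


# -- archive I/O -------------------------------------------------------------

def save_dataset(path, dataset: SyntheticDataset) -> None:
    """One compressed array container per dataset plus a JSON manifest."""
    path = Path(path)
    np.savez_compressed(
        path, X=dataset.X, y=dataset.y,
        truth=json.dumps({k: np.asarray(v).tolist() for k, v in dataset.truth.items()}))
    manifest = path.with_suffix(".manifest.json")
    manifest.write_text(json.dumps({"config": asdict(dataset.config)}, indent=2))


def load_dataset(path) -> SyntheticDataset:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path, allow_pickle=False) as archive:
        X, y = archive["X"], archive["y"]
        truth = {k: np.asarray(v) for k, v in json.loads(str(archive["truth"])).items()}
    manifest = path.with_suffix("").with_suffix(".manifest.json")
    cfg_raw = json.loads(manifest.read_text())["config"]
    cfg_raw["image_size"] = tuple(cfg_raw["image_size"])
    return SyntheticDataset(X=X, y=y, truth=truth, config=SyntheticConfig(**cfg_raw))


def load_nifti_stack(path) -> np.ndarray:
    """Read one subject's label-map stack from a NIfTI volume whose last
    axis is the frame axis; returns (frames, height, width) integers."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D (H, W, frames) volume, got {vol.shape}")
    return np.moveaxis(vol, -1, 0).astype(np.uint8)


def export_nifti(dataset: SyntheticDataset, out_dir) -> list[Path]:
    """Write each subject's label stack as a NIfTI volume (frames as the
    last axis)."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(dataset)):
        vol = np.moveaxis(dataset.X[i], 0, -1).astype(np.uint8)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        p = out_dir / f"subject_{i:04d}.nii"
        nib.save(img, str(p))
        paths.append(p)
    return paths
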