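"""Shared fixtures: random prediction sets and a small trained model."""

import numpy as np
import pytest

from calaware.calibration import PredictionSet
from calaware.model import CineVAEClassifier
from calaware.synthetic import SyntheticConfig, generate_dataset, split

#: Small, quickly learnable phantom: strong effect, little overlap.
TINY = SyntheticConfig(n_subjects=160, frames=4, image_size=(32, 32),
                       effect_size=0.25, noise_sd=0.02, label_flip_rate=0.0, seed=7)

TINY_MODEL_KW = dict(latent_dim=8, hidden=32, lr_clf=3e-3)


def random_prediction_set(rng: np.random.Generator, n: int | None = None) -> PredictionSet:
    n = n or int(rng.integers(5, 60))
    p_pos = rng.random(n)
    labels = rng.integers(0, 2, n)
    return PredictionSet.from_positive_probs(p_pos, labels)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(TINY)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return split(tiny_dataset, (0.6, 0.15, 0.25), seed=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_split):
    """A baseline model trained on the separable phantom."""
    ds, idx = tiny_dataset, tiny_split
    model = CineVAEClassifier(strategy="baseline", epochs=15, random_state=11,
                              **TINY_MODEL_KW)
    model.fit(ds.X[idx["train"]], ds.y[idx["train"]],
              X_val=ds.X[idx["val"]], y_val=ds.y[idx["val"]])
    return model
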