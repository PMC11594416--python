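"""Shared fixtures: a fast trained toy network on small oriented gratings,
and a stub observer for plumbing tests that need no trained CNN."""

import numpy as np
import pytest

from sdtnet import stimuli
from sdtnet.network import ConvNetClassifier


def make_tiny_gratings(n: int, seed: int, size: int = 20,
                       contrast: float = 1.0, noise_sd: float = 0.15):
    """Easy +/-45 deg grating discrimination at a small canvas size."""
    rng = np.random.default_rng(seed)
    X = np.empty((n, size, size), np.float32)
    y = np.empty(n, np.int64)
    for i in range(n):
        label = int(rng.random() < 0.5)
        ori = 135.0 if label == 1 else 45.0
        X[i] = stimuli.render_gabor(ori, contrast, size=size,
                                    noise_sd=noise_sd,
                                    rng=np.random.default_rng(seed + 31 * i + 1))
        y[i] = label
    return X, y


@pytest.fixture(scope="session")
def tiny_data():
    X, y = make_tiny_gratings(400, seed=5)
    Xv, yv = make_tiny_gratings(120, seed=6)
    return X, y, Xv, yv


@pytest.fixture(scope="session")
def tiny_net(tiny_data):
    X, y, Xv, yv = tiny_data
    net = ConvNetClassifier(conv_filters=(3, 4), dense_units=8, epochs=12,
                            random_state=2)
    net.fit(X, y, validation_data=(Xv, yv))
    return net


class StubObserver:
    """Duck-typed stand-in for a trained network: maps images to logits
    with a fixed linear readout of mean-intensity asymmetry plus seeded
    noise, so downstream plumbing can run without CNN training."""

    def __init__(self, gain: float = 40.0, noise: float = 0.5, seed: int = 0):
        self.gain = gain
        self.noise = noise
        self.seed = seed
        self._count = 0

    def decision_function(self, X):
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[..., None]
        h = X.shape[1]
        upper = X[:, : h // 2].mean(axis=(1, 2, 3))
        lower = X[:, h // 2:].mean(axis=(1, 2, 3))
        rng = np.random.default_rng(self.seed + self._count)
        self._count += 1
        return self.gain * (upper - lower) + rng.normal(0, self.noise, len(X))

    def predict_proba(self, X):
        z = self.decision_function(X)
        a = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - a, a])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))
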