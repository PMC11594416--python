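"""The 4-layer CNN binary classifier, as a scikit-learn estimator.

Architecture: conv3x3 -> ReLU -> maxpool2x2 -> conv3x3 -> ReLU ->
maxpool2x2 -> flatten -> dense(64, ReLU) -> dense(1, sigmoid).  Trained
with binary cross-entropy and Adam (lr 0.001, eps 1e-8), batch size 32,
up to 25 epochs with early stopping (patience 10 on validation loss; by
default the final weights are kept, as common toolchains do — restoring
the best-epoch weights is available via ``restore_best`` but freezes the
network at its least-confident early state, muting the overconfidence
these models characteristically develop).  The pre-sigmoid output-layer
logit ``z`` is exposed by
:meth:`ConvNetClassifier.decision_function` and serves as the network's
"evidence" variable in all downstream analyses; the sigmoid activation
``a = 1/(1+exp(-z))`` is the confidence substrate.

Implemented directly on NumPy (see :mod:`sdtnet._nn`); training is exactly
reproducible given ``random_state``, the data, and the configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import F32

__all__ = ["ConvNetClassifier", "train_ensemble", "save_ensemble", "load_ensemble"]


class ConvNetClassifier:
    """Small convolutional binary classifier with a sigmoid output unit.

    Parameters
    ----------
    conv_filters : tuple of int
        Filter counts of the two convolutional layers.
    dense_units : int
        Width of the penultimate fully connected layer.
    epochs, batch_size, learning_rate, epsilon, patience
        Training protocol; defaults follow the study protocol (25 epochs,
        batch 32, Adam lr 1e-3 eps 1e-8, early stopping patience 10).
    random_state : int or None
        Seed for weight initialization and batch shuffling.

    Attributes
    ----------
    weights_ : dict of ndarray
        Fitted parameters.
    history_ : list of dict
        Per-epoch train loss/accuracy and validation loss/accuracy.
    val_accuracy_ : float or None
        Accuracy on the validation set with the fitted weights.
    n_epochs_ : int
        Number of epochs actually run.
    """

    def __init__(self, conv_filters=(4, 8), dense_units=64, epochs=25,
                 batch_size=32, learning_rate=1e-3, epsilon=1e-8,
                 patience=10, restore_best=False, random_state=None):
        self.conv_filters = conv_filters
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epsilon = epsilon
        self.patience = patience
        self.restore_best = restore_best
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def get_params(self, deep=True):
        return {
            "conv_filters": self.conv_filters, "dense_units": self.dense_units,
            "epochs": self.epochs, "batch_size": self.batch_size,
            "learning_rate": self.learning_rate, "epsilon": self.epsilon,
            "patience": self.patience, "restore_best": self.restore_best,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _as_nchw(X) -> np.ndarray:
        X = np.asarray(X, dtype=F32)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4:
            raise ValueError(f"expected (N,H,W[,C]) images, got shape {X.shape}")
        # images arrive in [0,1]; feed them centered about mid-gray.  The
        # fixed shift (no data-dependent statistics) removes the large
        # common-mode drive that can push the whole dense layer into the
        # dead-ReLU absorbing state early in a long epoch
        return np.ascontiguousarray(X.transpose(0, 3, 1, 2)) - F32(0.5)

    def _init_weights(self, H: int, W: int, C: int, rng: np.random.Generator) -> dict:
        f1, f2 = self.conv_filters
        h1, w1 = (H - 2) // 2, (W - 2) // 2
        h2, w2 = (h1 - 2) // 2, (w1 - 2) // 2
        flat = h2 * w2 * f2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"input {H}x{W} too small for the architecture")
        # He init and small positive biases for the ReLU layers: with
        # uncentered [0,1] inputs and Adam, zero biases let whole layers
        # die (all-negative pre-activations) early in long epochs
        return {
            "W1": _nn.he_uniform(rng, (f1, C, 3, 3), 9 * C),
            "b1": np.full(f1, 0.05, F32),
            "W2": _nn.he_uniform(rng, (f2, f1, 3, 3), 9 * f1),
            "b2": np.full(f2, 0.05, F32),
            "W3": _nn.he_uniform(rng, (flat, self.dense_units), flat),
            "b3": np.full(self.dense_units, 0.05, F32),
            "W4": _nn.glorot_uniform(rng, (self.dense_units, 1), self.dense_units, 1),
            "b4": np.zeros(1, F32),
        }

    def _forward(self, X: np.ndarray, weights=None, train: bool = False):
        w = weights or self.weights_
        a1, cc1 = _nn.conv_forward(X, w["W1"], w["b1"], relu=True)
        p1, cp1 = _nn.maxpool_forward(a1)
        a2, cc2 = _nn.conv_forward(p1, w["W2"], w["b2"], relu=True)
        p2, cp2 = _nn.maxpool_forward(a2)
        flat = p2.reshape(p2.shape[0], -1)
        h = flat @ w["W3"] + w["b3"]
        hr = np.maximum(h, 0)
        z = (hr @ w["W4"] + w["b4"])[:, 0]
        if not train:
            return z
        cache = (cc1, cp1, cc2, cp2, p2.shape, flat, h, hr)
        return z, cache

    def _backward(self, dz: np.ndarray, w: dict, cache) -> dict:
        cc1, cp1, cc2, cp2, p2shape, flat, h, hr = cache
        g = {}
        dz = dz[:, None].astype(F32)
        g["W4"] = hr.T @ dz
        g["b4"] = dz.sum(0)
        dhr = dz @ w["W4"].T
        dh = (dhr * (h > 0)).astype(F32)
        g["W3"] = flat.T @ dh
        g["b3"] = dh.sum(0)
        dflat = dh @ w["W3"].T
        dp2 = dflat.reshape(p2shape)
        da2 = _nn.maxpool_backward(dp2, cp2)
        dp1, g["W2"], g["b2"] = _nn.conv_backward(da2, w["W2"], cc2, need_dx=True)
        da1 = _nn.maxpool_backward(dp1, cp1)
        _, g["W1"], g["b1"] = _nn.conv_backward(da1, w["W1"], cc1, need_dx=False)
        return g

    def _batched_logits(self, X: np.ndarray, weights=None, batch: int = 64) -> np.ndarray:
        outs = [self._forward(X[i:i + batch], weights)
                for i in range(0, len(X), batch)]
        return np.concatenate(outs) if outs else np.zeros(0)

    # -- estimator API ------------------------------------------------------

    @staticmethod
    def _is_collapsed(z: np.ndarray, accuracy: float) -> bool:
        """Dead-network detection: ReLU layers can fall into an absorbing
        all-negative state under Adam, leaving a constant logit and chance
        accuracy with zero gradient everywhere.  Constant logits separate
        this from an ordinary slow learner."""
        return accuracy < 0.55 and float(np.std(z)) < 1e-3

    def fit(self, X, y, validation_data=None):
        """Train on images ``X`` (N,H,W[,C]) with binary labels ``y``.

        ``validation_data=(Xval, yval)`` drives early stopping and
        best-weight restoration; without it the full epoch budget is used.
        A training run that collapses into the dead-ReLU chance state is
        detected and restarted from a reseeded initialization (at most 3
        restarts, all derived from ``random_state``); ``n_restarts_``
        records how many were needed and ``collapsed_`` whether the final
        run still ended dead.
        """
        X = self._as_nchw(X)
        y = np.asarray(y, dtype=np.float64)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        n, C, H, W = X.shape
        self.input_shape_ = (C, H, W)
        for attempt in range(4):
            self._fit_once(X, y, validation_data, attempt)
            if not self.collapsed_:
                break
        self.n_restarts_ = attempt
        if self.collapsed_:
            import warnings
            warnings.warn("training ended in the chance-level collapsed "
                          "state after 3 restarts")
        return self

    def _fit_once(self, X, y, validation_data, attempt: int):
        n, C, H, W = X.shape
        seed = 0 if self.random_state is None else self.random_state
        rng = np.random.default_rng(seed if attempt == 0 else (attempt, seed))
        weights = self._init_weights(H, W, C, rng)
        opt = _nn.Adam(weights, learning_rate=self.learning_rate,
                       epsilon=self.epsilon)
        has_val = validation_data is not None
        if has_val:
            Xval = self._as_nchw(validation_data[0])
            yval = np.asarray(validation_data[1], dtype=np.float64)
        best_loss, best_weights, best_epoch = np.inf, None, -1
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                z, cache = self._forward(xb, weights, train=True)
                a = _nn.sigmoid(z)
                loss = _nn.bce_loss(a, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (loss={loss}) at epoch {epoch}"
                    )
                ep_loss += loss * len(idx)
                ep_correct += int(np.sum((a >= 0.5) == (yb == 1)))
                dz = (a - yb) / len(idx)  # d(BCE)/dz through the sigmoid
                grads = self._backward(dz, weights, cache)
                opt.step(weights, grads)
            rec = {"epoch": epoch, "loss": ep_loss / n, "accuracy": ep_correct / n}
            if has_val:
                zv = self._batched_logits(Xval, weights)
                av = _nn.sigmoid(zv)
                rec["val_loss"] = _nn.bce_loss(av, yval)
                rec["val_accuracy"] = float(np.mean((av >= 0.5) == (yval == 1)))
                if rec["val_loss"] < best_loss:
                    best_loss = rec["val_loss"]
                    best_weights = {k: v.copy() for k, v in weights.items()}
                    best_epoch = epoch
            self.history_.append(rec)
            if has_val and epoch >= 2 and self._is_collapsed(zv, rec["val_accuracy"]):
                break  # dead network: zero gradients, no point continuing
            if has_val and epoch - best_epoch >= self.patience:
                break
        if has_val and self.restore_best and best_weights is not None:
            weights = best_weights
        self.weights_ = weights
        self.n_epochs_ = len(self.history_)
        self.best_epoch_ = best_epoch if has_val else self.n_epochs_ - 1
        if has_val:
            zv = self._batched_logits(Xval, weights)
            self.val_accuracy_ = float(np.mean((_nn.sigmoid(zv) >= 0.5) == (yval == 1)))
            self.collapsed_ = self._is_collapsed(zv, self.val_accuracy_)
        else:
            self.val_accuracy_ = None
            zt = self._batched_logits(X[: min(n, 256)], weights)
            self.collapsed_ = self._is_collapsed(
                zt, float(np.mean((_nn.sigmoid(zt) >= 0.5) == (y[: min(n, 256)] == 1))))

    def decision_function(self, X) -> np.ndarray:
        """Output-layer logits ``z`` (the evidence variable)."""
        self._check_fitted()
        X = self._as_nchw(X)
        if len(X) and X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"input shape {X.shape[1:]} != fitted {self.input_shape_}"
            )
        return self._batched_logits(X)

    def predict_proba(self, X) -> np.ndarray:
        a = _nn.sigmoid(self.decision_function(X))
        return np.column_stack([1 - a, a])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise RuntimeError("classifier is not fitted")

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Weights as .npz plus a JSON sidecar with config and metadata."""
        self._check_fitted()
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.weights_)
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "input_shape": list(self.input_shape_),
            "val_accuracy": self.val_accuracy_,
            "n_epochs": self.n_epochs_,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "ConvNetClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        params = meta["params"]
        params["conv_filters"] = tuple(params["conv_filters"])
        net = cls(**params)
        with np.load(path.with_suffix(".npz")) as data:
            net.weights_ = {k: data[k] for k in data.files}
        net.input_shape_ = tuple(meta["input_shape"])
        net.val_accuracy_ = meta["val_accuracy"]
        net.n_epochs_ = meta["n_epochs"]
        net.classes_ = np.array([0, 1])
        net.history_ = []
        return net


def train_ensemble(X, y, Xval, yval, n_instances: int = 25,
                   base_seed: int = 1000, **net_kwargs) -> list:
    """Train ``n_instances`` networks on the same data, differing only in
    the seed used for weight initialization and batch shuffling."""
    nets = []
    for i in range(n_instances):
        net = ConvNetClassifier(random_state=base_seed + i, **net_kwargs)
        net.fit(X, y, validation_data=(Xval, yval))
        nets.append(net)
    return nets


def save_ensemble(nets, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, net in enumerate(nets):
        stem = outdir / f"instance_{i:03d}"
        net.save(stem)
        rows.append({"instance": i, "seed": net.random_state,
                     "val_accuracy": net.val_accuracy_})
    manifest = outdir / "ensemble.json"
    manifest.write_text(json.dumps(rows, indent=1))
    return manifest


def load_ensemble(outdir) -> list:
    outdir = Path(outdir)
    rows = json.loads((outdir / "ensemble.json").read_text())
    return [ConvNetClassifier.load(outdir / f"instance_{r['instance']:03d}")
            for r in rows]
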