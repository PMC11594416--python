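"""Network estimator: forward/backward correctness, determinism, the
sigmoid-logit link, persistence, and sklearn protocol compliance."""

import numpy as np
import pytest

from sdtnet import _nn
from sdtnet.network import ConvNetClassifier, train_ensemble

from conftest import make_tiny_gratings


class TestEstimatorContract:
    def test_logit_activation_link(self, tiny_net, tiny_data):
        X = tiny_data[2][:40]
        z = tiny_net.decision_function(X)
        a = tiny_net.predict_proba(X)[:, 1]
        assert np.all((a >= 0) & (a <= 1))
        assert np.all((a > 0) & (a < 1) | (np.abs(z) > 30))
        assert np.allclose(a, 1.0 / (1.0 + np.exp(-z.astype(np.float64))),
                           rtol=1e-12)
        # monotone link
        order = np.argsort(z)
        assert np.all(np.diff(a[order]) >= 0)

    def test_inference_is_deterministic(self, tiny_net, tiny_data):
        X = tiny_data[0][:16]
        assert np.array_equal(tiny_net.decision_function(X),
                              tiny_net.decision_function(X))

    def test_empty_batch(self, tiny_net):
        assert tiny_net.decision_function(np.zeros((0, 20, 20))).shape == (0,)
        assert tiny_net.predict(np.zeros((0, 20, 20))).shape == (0,)

    def test_shape_mismatch_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.decision_function(np.zeros((2, 30, 30)))

    def test_get_set_params_and_clone(self):
        from sklearn.base import clone

        net = ConvNetClassifier(conv_filters=(2, 3), random_state=7)
        p = net.get_params()
        assert p["conv_filters"] == (2, 3) and p["random_state"] == 7
        net.set_params(epochs=5)
        assert net.epochs == 5
        with pytest.raises(ValueError):
            net.set_params(bogus=1)
        c = clone(net)
        assert c.get_params() == net.get_params()

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            ConvNetClassifier().decision_function(np.zeros((1, 20, 20)))

    def test_rejects_nonbinary_labels(self):
        net = ConvNetClassifier(epochs=1)
        with pytest.raises(ValueError):
            net.fit(np.zeros((4, 20, 20)), [0, 1, 2, 1])


class TestTraining:
    def test_same_seed_reproduces_training_exactly(self):
        X, y = make_tiny_gratings(96, seed=3)
        runs = []
        for _ in range(2):
            net = ConvNetClassifier(conv_filters=(2, 3), dense_units=6,
                                    epochs=2, random_state=11)
            net.fit(X, y)
            runs.append(net)
        assert runs[0].history_[0]["loss"] == runs[1].history_[0]["loss"]
        for k in runs[0].weights_:
            assert np.array_equal(runs[0].weights_[k], runs[1].weights_[k])

    def test_learns_structure_but_not_shuffled_labels(self, tiny_data):
        X, y, Xv, yv = tiny_data
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        real = ConvNetClassifier(conv_filters=(3, 4), dense_units=8,
                                 epochs=12, random_state=1)
        real.fit(X, y, validation_data=(Xv, yv))
        shuf = ConvNetClassifier(conv_filters=(3, 4), dense_units=8,
                                 epochs=12, random_state=1)
        shuf.fit(X, y_shuf, validation_data=(Xv, yv))
        assert real.val_accuracy_ - shuf.val_accuracy_ > 0.30

    def test_collapse_detector_distinguishes_dead_from_slow(self):
        rng = np.random.default_rng(0)
        z_dead = np.zeros(200)
        z_live = rng.normal(0, 0.5, 200)
        assert ConvNetClassifier._is_collapsed(z_dead, 0.50)
        assert not ConvNetClassifier._is_collapsed(z_live, 0.50)
        assert not ConvNetClassifier._is_collapsed(z_dead, 0.90)

    def test_healthy_training_needs_no_restart(self, tiny_net):
        assert tiny_net.n_restarts_ == 0
        assert not tiny_net.collapsed_

    def test_identical_classes_stay_at_chance(self):
        rng = np.random.default_rng(2)
        X = np.repeat(rng.random((1, 20, 20)).astype(np.float32), 80, axis=0)
        y = np.tile([0, 1], 40)
        net = ConvNetClassifier(conv_filters=(2, 3), dense_units=6,
                                epochs=2, random_state=0)
        net.fit(X, y, validation_data=(X[:20], y[:20]))
        assert abs(net.val_accuracy_ - 0.5) <= 0.1

    def test_early_stopping_restore_best_option(self, tiny_data):
        X, y, Xv, yv = tiny_data
        net = ConvNetClassifier(conv_filters=(2, 3), dense_units=6, epochs=4,
                                patience=1, restore_best=True, random_state=3)
        net.fit(X[:120], y[:120], validation_data=(Xv, yv))
        best = min(h["val_loss"] for h in net.history_)
        zv = net.decision_function(Xv)
        restored = _nn.bce_loss(_nn.sigmoid(zv), yv.astype(float))
        assert abs(restored - best) < 1e-9
        # default keeps the final weights instead
        net2 = ConvNetClassifier(conv_filters=(2, 3), dense_units=6, epochs=4,
                                 patience=10, random_state=3)
        net2.fit(X[:120], y[:120], validation_data=(Xv, yv))
        zv2 = net2.decision_function(Xv)
        final = _nn.bce_loss(_nn.sigmoid(zv2), yv.astype(float))
        assert abs(final - net2.history_[-1]["val_loss"]) < 1e-9

    def test_train_ensemble_distinct_seeds_distinct_nets(self):
        X, y = make_tiny_gratings(64, seed=8)
        Xv, yv = make_tiny_gratings(32, seed=9)
        nets = train_ensemble(X, y, Xv, yv, n_instances=2, base_seed=50,
                              conv_filters=(2, 3), dense_units=6, epochs=1)
        assert len(nets) == 2
        assert nets[0].random_state != nets[1].random_state
        assert not np.array_equal(nets[0].weights_["W1"], nets[1].weights_["W1"])


def test_gradients_match_finite_differences():
    """Backprop through conv/pool/dense agrees with numerical gradients."""
    net = ConvNetClassifier(conv_filters=(2, 3), dense_units=5, random_state=0)
    rng = np.random.default_rng(0)
    X = rng.random((4, 1, 14, 14)).astype(np.float32)
    y = rng.integers(0, 2, 4).astype(float)
    w = net._init_weights(14, 14, 1, rng)

    def loss_at():
        z = net._forward(X, w)
        return _nn.bce_loss(_nn.sigmoid(z), y)

    z, cache = net._forward(X, w, train=True)
    dz = (_nn.sigmoid(z) - y) / len(y)
    g = net._backward(dz, w, cache)
    rng2 = np.random.default_rng(1)
    for k in ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4"):
        flat = w[k].reshape(-1)
        gflat = g[k].reshape(-1)
        idx = rng2.choice(flat.size, size=min(12, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            eps = 1e-3
            flat[i] = orig + eps
            lp = loss_at()
            flat[i] = orig - eps
            lm = loss_at()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            if max(abs(num), abs(gflat[i])) > 1e-3:
                assert abs(num - gflat[i]) / max(abs(num), abs(gflat[i])) < 0.08, (k, i)


def test_save_load_roundtrip(tmp_path, tiny_net, tiny_data):
    X = tiny_data[2][:20]
    tiny_net.save(tmp_path / "net")
    loaded = ConvNetClassifier.load(tmp_path / "net")
    assert np.array_equal(loaded.decision_function(X),
                          tiny_net.decision_function(X))
    assert loaded.val_accuracy_ == tiny_net.val_accuracy_
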