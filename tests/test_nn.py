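import numpy as np
import pytest
from scipy.signal import correlate

from cliffpix.classifier import CNNClassifier, ModelConfig, build_model, reduced_config
from cliffpix.errors import DataError, UsageError
from cliffpix.nn import Adam, Conv2D, Dense, MaxPool2, softmax, softmax_cross_entropy

TINY = ModelConfig(input_shape=(10, 18, 3), dense_units=6, seed=3, epochs=2, batch_size=4)


def tiny_model(**overrides):
    cfg = ModelConfig(**{**TINY.__dict__, **overrides})
    return CNNClassifier(cfg)


class TestConv:
    def test_forward_matches_scipy_correlate(self):
        rng = np.random.default_rng(0)
        conv = Conv2D(5, 2, 3, "c", rng)
        x = rng.standard_normal((2, 9, 11, 2)).astype(np.float32)
        out = conv.forward(x)
        for n in range(2):
            for co in range(3):
                ref = sum(
                    correlate(
                        x[n, :, :, ci].astype(np.float64),
                        conv.W[ci, :, :, co].astype(np.float64),
                        mode="same",
                    )
                    for ci in range(2)
                )
                assert np.allclose(out[n, :, :, co], ref + conv.b[co], atol=1e-5)

    def test_even_kernel_rejected(self):
        with pytest.raises(UsageError):
            Conv2D(4, 1, 1, "c", np.random.default_rng(0))


class TestGradients:
    @pytest.mark.parametrize("layer_kind", ["conv", "dense"])
    def test_linear_layer_gradients_match_finite_differences(self, layer_kind):
        """For the (locally linear) parametric layers a central
        difference of a random linear functional of the output recovers
        the analytic parameter and input gradients."""
        rng = np.random.default_rng(1)
        if layer_kind == "conv":
            layer = Conv2D(3, 2, 4, "c", rng)
            x = rng.standard_normal((2, 6, 7, 2)).astype(np.float32)
        else:
            layer = Dense(10, 4, "d", rng)
            x = rng.standard_normal((3, 10)).astype(np.float32)
        probe = rng.standard_normal(layer.forward(x).shape).astype(np.float32)

        def loss():
            return float((layer.forward(x) * probe).sum())

        layer.forward(x)
        dx = layer.backward(probe)
        grads = [g.copy() for _, g in layer.params()] + [dx.copy()]
        tensors = [p for p, _ in layer.params()] + [x]
        for tensor, grad in zip(tensors, grads):
            flat, gflat = tensor.ravel(), grad.ravel()
            for i in rng.choice(flat.size, size=min(12, flat.size), replace=False):
                eps = 1e-2
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - gflat[i]) <= 1e-2 * max(1.0, abs(numeric))

    def test_softmax_cross_entropy_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        logits = rng.standard_normal((4, 2)).astype(np.float64)
        y = np.zeros((4, 2))
        y[np.arange(4), rng.integers(0, 2, size=4)] = 1.0
        _, analytic = softmax_cross_entropy(logits, y)
        for i in range(4):
            for j in range(2):
                eps = 1e-5
                lp = softmax_cross_entropy(logits + eps * np.eye(4)[:, [i]] @ np.eye(2)[[j]], y)[0]
                lm = softmax_cross_entropy(logits - eps * np.eye(4)[:, [i]] @ np.eye(2)[[j]], y)[0]
                assert (lp - lm) / (2 * eps) == pytest.approx(analytic[i, j], abs=1e-4)

    def test_maxpool_routes_gradient_to_maxima(self):
        pool = MaxPool2()
        x = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
        out = pool.forward(x)
        assert out.ravel().tolist() == [5, 7, 13, 15]
        dx = pool.backward(np.ones_like(out))
        assert dx.ravel().tolist() == [
            0, 0, 0, 0,
            0, 1, 0, 1,
            0, 0, 0, 0,
            0, 1, 0, 1,
        ]

    def test_adam_single_step_hand_computed(self):
        p = np.array([1.0], dtype=np.float32)
        g = np.array([0.5], dtype=np.float32)
        opt = Adam(lr=0.1, beta1=0.9, beta2=0.999, eps=1e-7)
        opt.step([(p, g)])
        # bias-corrected first step: m_hat = g, v_hat = g^2, so the update
        # is lr * g / (|g| + eps) = lr in magnitude
        m_hat, v_hat = 0.5, 0.25
        assert p[0] == pytest.approx(1.0 - 0.1 * m_hat / (np.sqrt(v_hat) + 1e-7), rel=1e-3)


class TestModelContracts:
    def test_output_shape_and_softmax_normalization(self):
        model = tiny_model()
        x = np.random.default_rng(0).random((5, 10, 18, 3), dtype=np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_same_seed_same_initial_weights(self):
        a, b = tiny_model(), tiny_model()
        for (pa, _), (pb, _) in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa, pb)

    def test_different_seed_different_weights(self):
        a, b = tiny_model(), tiny_model(seed=4)
        assert any(
            not np.array_equal(pa, pb)
            for (pa, _), (pb, _) in zip(a.net.params(), b.net.params())
        )

    def test_invalid_dropout_rate_is_usage_error(self):
        with pytest.raises(UsageError):
            build_model(ModelConfig(dropout_rate=1.5))

    def test_wrong_input_shape_is_usage_error(self):
        model = tiny_model()
        with pytest.raises(UsageError):
            model.predict_proba(np.zeros((1, 8, 8, 3), dtype=np.float32))

    def test_reduced_profile_geometry(self):
        cfg = reduced_config()
        assert cfg.input_shape == (150, 450, 3)
        assert cfg.epochs <= 10


class TestTraining:
    def _data(self, n=24):
        rng = np.random.default_rng(2)
        x = rng.random((n, 10, 18, 3), dtype=np.float32)
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        # plant a separable signal
        x[y == 1, 2:6, 2:6, :] *= 0.1
        return x, y

    def test_loss_decreases_on_separable_data(self):
        x, y = self._data()
        model = tiny_model(epochs=10)
        history = model.fit(x, y)
        assert len(history) == 10
        assert history[-1] < history[0]
        assert np.isfinite(history).all()

    def test_zero_epochs_leaves_weights_unchanged(self):
        x, y = self._data()
        model = tiny_model(epochs=0)
        before = [p.copy() for p, _ in model.net.params()]
        assert model.fit(x, y) == []
        for (p, _), prev in zip(model.net.params(), before):
            assert np.array_equal(p, prev)

    def test_training_is_bit_reproducible(self):
        x, y = self._data()
        a, b = tiny_model(epochs=3), tiny_model(epochs=3)
        ha, hb = a.fit(x, y), b.fit(x, y)
        assert ha == hb
        for (pa, _), (pb, _) in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa, pb)

    def test_single_class_input_is_data_error(self):
        x, _ = self._data()
        with pytest.raises(DataError):
            tiny_model().fit(x, np.zeros(len(x), dtype=int))

    def test_prediction_order_preserved(self):
        x, y = self._data()
        model = tiny_model(epochs=2)
        model.fit(x, y)
        records = model.predict(x[:4], mmp_ids=["p", "q", "r", "s"])
        assert [r.mmp_id for r in records] == ["p", "q", "r", "s"]
        for r in records:
            assert r.p_ac + r.p_non_ac == pytest.approx(1.0, abs=1e-6)
            assert r.predicted_label == ("AC" if r.p_ac >= r.p_non_ac else "NON_AC")

    def test_save_load_round_trip(self, tmp_path):
        x, y = self._data()
        model = tiny_model(epochs=2)
        model.fit(x, y)
        model.save(tmp_path / "model")
        clone = CNNClassifier.load(tmp_path / "model")
        assert np.array_equal(model.predict_proba(x[:3]), clone.predict_proba(x[:3]))
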