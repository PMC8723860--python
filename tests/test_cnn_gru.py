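"""CNN-GRU hybrid: building-block arithmetic, a hand-traced forward pass
and a finite-difference check of the analytic gradients."""

import numpy as np
import pytest
from scipy.special import expit as sigmoid

from edlcdss import (
    CNNGRUClassifier,
    avg_pool,
    conv1d_forward,
    gru_step,
    softmax_output,
)


def tiny_model(rng_seed=0, epochs=0):
    """<= 50-parameter model used for hand traces and gradient checks."""
    m = CNNGRUClassifier(
        conv_layers=((1, 3),), pool_width=2, gru_input_size=2,
        gru_hidden_size=2, gru_output_size=2, n_gru_units=1,
        epochs=epochs, seed=rng_seed,
    )
    return m


class TestConv:
    def test_delta_kernel_recovers_centered_slice(self):
        x = np.arange(1.0, 11.0)[None, :]
        K = np.zeros((1, 1, 5))
        K[0, 0, 2] = 1.0
        out = conv1d_forward(x, K, np.zeros(1), apply_sigmoid=False)
        np.testing.assert_array_equal(out[0], x[0, 2:-2])

    def test_box_kernel_hand_sum(self):
        x = np.array([[1.0, 2, 3, 4, 5, 6]])
        K = np.ones((1, 1, 5))
        out = conv1d_forward(x, K, np.zeros(1), apply_sigmoid=False)
        np.testing.assert_array_equal(out[0], [15.0, 20.0])

    def test_sigmoid_output_in_unit_interval(self, rng):
        x = rng.random((3, 20))
        K = rng.normal(size=(3, 4, 5))
        out = conv1d_forward(x, K, rng.normal(size=4))
        assert ((out > 0) & (out < 1)).all()

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="shorter than kernel"):
            conv1d_forward(np.ones((1, 3)), np.ones((1, 1, 5)), np.zeros(1))

    @pytest.mark.parametrize("length", range(5, 65))
    def test_length_bookkeeping(self, length):
        x = np.ones((1, length))
        out = conv1d_forward(x, np.ones((1, 2, 5)), np.zeros(2))
        assert out.shape == (2, length - 4)
        if (length - 4) // 2 == 0:  # everything would be remainder
            with pytest.raises(ValueError, match="pool"):
                avg_pool(out, 2)
        else:
            assert avg_pool(out, 2).shape == (2, (length - 4) // 2)


class TestPool:
    def test_hand_average(self):
        np.testing.assert_array_equal(
            avg_pool(np.array([1.0, 3, 5, 7]), 2), [2.0, 6.0]
        )

    def test_constant_map_unchanged(self):
        np.testing.assert_array_equal(avg_pool(np.full(8, 3.5), 2),
                                      np.full(4, 3.5))

    def test_trailing_remainder_discarded(self):
        np.testing.assert_array_equal(avg_pool(np.array([1.0, 2, 3]), 2),
                                      [1.5])


class TestGRUStep:
    def test_zero_weights_halve_previous_state(self):
        H, I = 3, 2
        h_prev = np.array([0.4, -0.2, 1.0])
        out = gru_step(h_prev, np.zeros(I), np.zeros((H, H + I)),
                       np.zeros((H, H + I)), np.zeros((H, H + I)))
        np.testing.assert_allclose(out, 0.5 * h_prev)

    def test_closed_update_gate_freezes_state(self):
        # drive z -> 0 through a constant-one input coordinate
        H = 2
        h_prev = np.array([0.7, -0.3])
        x = np.array([1.0])
        W_z = np.zeros((H, H + 1))
        W_z[:, -1] = -30.0  # z = sigmoid(-30) ~ 0
        rng = np.random.default_rng(0)
        out = gru_step(h_prev, x, W_z, rng.normal(size=(H, H + 1)),
                       rng.normal(size=(H, H + 1)))
        np.testing.assert_allclose(out, h_prev, atol=1e-10)

    def test_state_bounded_by_convexity(self, rng):
        H, I = 4, 3
        for _ in range(50):
            h_prev = rng.uniform(-1, 1, H)
            x = rng.normal(size=I)
            out = gru_step(h_prev, x, rng.normal(size=(H, H + I)),
                           rng.normal(size=(H, H + I)),
                           rng.normal(size=(H, H + I)))
            assert (np.abs(out) <= np.maximum(np.abs(h_prev), 1.0) + 1e-12
                    ).all()


class TestSoftmax:
    def test_equal_logits_uniform(self):
        p = softmax_output(np.ones(3), np.ones((4, 3)))
        np.testing.assert_allclose(p, 0.25)

    def test_log_odds_closed_form(self):
        p = softmax_output(np.array([1.0]),
                           np.array([[np.log(1.0)], [np.log(3.0)]]))
        np.testing.assert_allclose(p, [0.25, 0.75])

    def test_shift_invariance_and_normalisation(self, rng):
        h = rng.normal(size=5)
        w = rng.normal(size=(3, 5))
        p = softmax_output(h, w)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        # shift every logit by the same constant c: add c*h/(h.h) per row
        c = 3.7
        w_shift = w + c * h / (h @ h)
        np.testing.assert_allclose(softmax_output(h, w_shift), p, atol=1e-10)


class TestForward:
    def test_posterior_normalised_and_deterministic(self, separable_Xy):
        X, y = separable_Xy
        m = CNNGRUClassifier(conv_layers=((4, 5),), gru_hidden_size=8,
                             gru_input_size=4, n_gru_units=4, epochs=0,
                             seed=0).fit(X[:50], y[:50])
        p1 = m.predict_proba(X[:10])
        p2 = m.predict_proba(X[:10])
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-12)

    def test_manual_trace_single_map(self):
        """Hand-computed forward pass on a 6-feature row with one conv map."""
        m = tiny_model()
        X = np.array([[0.1, 0.5, 0.9, 0.2, 0.6, 0.3],
                      [0.9, 0.1, 0.4, 0.8, 0.2, 0.7]])
        y = np.array([0, 1])
        m.fit(X, y)
        x = X[0]
        K, b = m.conv_kernels_[0][0, 0], m.conv_biases_[0][0]
        conv = sigmoid(np.array([
            x[i] * K[0] + x[i + 1] * K[1] + x[i + 2] * K[2] + b
            for i in range(4)
        ]))
        pooled = np.array([conv[:2].mean(), conv[2:].mean()])
        h = np.zeros(2)
        hx = np.concatenate([h, pooled])
        z = sigmoid(m.W_z_[0] @ hx)
        r = sigmoid(m.W_r_[0] @ hx)
        cand = np.tanh(m.W_[0] @ np.concatenate([r * h, pooled]))
        h = (1 - z) * h + z * cand
        o = np.tanh(m.W_out_[0] @ h + m.b_out_[0])
        logits = m.W_cls_[0] @ o + m.b_cls_[0]
        expect = np.exp(logits - logits.max())
        expect /= expect.sum()
        post, penult = m.forward(x)
        np.testing.assert_allclose(post, expect, atol=1e-12)
        np.testing.assert_allclose(penult, o, atol=1e-12)


class TestGradients:
    def test_analytic_matches_central_difference(self):
        """Backprop on the <= 50-parameter model agrees with central
        differences to 1e-4 relative."""
        rng = np.random.default_rng(0)
        m = tiny_model()
        X = rng.random((4, 6))
        y = np.array([0, 1, 0, 1])
        m.fit(X, y)
        T = (y[:, None] == m.classes_[None, :]).astype(float)
        _, grads = m._gradients(X, T)
        eps = 1e-6

        def numeric(arr, idx):
            old = arr[idx]
            arr[idx] = old + eps
            lp, _ = m._gradients(X, T)
            arr[idx] = old - eps
            lm, _ = m._gradients(X, T)
            arr[idx] = old
            return (lp - lm) / (2 * eps)

        n_params = 0
        for name in ("W_z_", "W_r_", "W_", "W_out_", "b_out_",
                     "W_cls_", "b_cls_"):
            arr, g = getattr(m, name), grads[name]
            n_params += arr.size
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                num = numeric(arr, idx)
                denom = max(1e-8, abs(num) + abs(g[idx]))
                assert abs(num - g[idx]) / denom < 1e-4, (name, idx)
        for l, (K, bk) in enumerate(zip(m.conv_kernels_, m.conv_biases_)):
            for arr, g in ((K, grads["conv_kernels_"][l]),
                           (bk, grads["conv_biases_"][l])):
                n_params += arr.size
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    num = numeric(arr, idx)
                    denom = max(1e-8, abs(num) + abs(g[idx]))
                    assert abs(num - g[idx]) / denom < 1e-4
        assert n_params <= 50


class TestTraining:
    def test_separable_fixture_training_accuracy(self, separable_Xy):
        X, y = separable_Xy
        m = CNNGRUClassifier(conv_layers=((4, 5),), gru_hidden_size=16,
                             gru_input_size=3, n_gru_units=4, epochs=30,
                             seed=0).fit(X, y)
        assert np.mean(m.predict(X) == y) >= 0.95

    def test_zero_epochs_near_chance(self, separable_Xy):
        X, y = separable_Xy
        m = CNNGRUClassifier(conv_layers=((4, 5),), gru_hidden_size=8,
                             gru_input_size=3, n_gru_units=4, epochs=0,
                             seed=0).fit(X, y)
        acc = np.mean(m.predict(X) == y)
        assert 0.3 <= acc <= 0.7

    def test_fixed_seed_reproducible(self, separable_Xy):
        X, y = separable_Xy
        kw = dict(conv_layers=((2, 5),), gru_hidden_size=4, gru_input_size=3,
                  n_gru_units=2, epochs=3, seed=4)
        a = CNNGRUClassifier(**kw).fit(X, y)
        b = CNNGRUClassifier(**kw).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X[:5]),
                                      b.predict_proba(X[:5]))
        np.testing.assert_array_equal(a.W_z_, b.W_z_)

    def test_feature_vector_shape(self, separable_Xy):
        X, y = separable_Xy
        m = CNNGRUClassifier(conv_layers=((4, 5),), gru_hidden_size=8,
                             gru_output_size=5, gru_input_size=3,
                             n_gru_units=4, epochs=0, seed=0).fit(X, y)
        fv = m.feature_vector(X[:3])
        assert fv.shape == (3, 4 * 5)


class TestPersistence:
    def test_archive_round_trip(self, tmp_path, separable_Xy):
        X, y = separable_Xy
        m = CNNGRUClassifier(conv_layers=((2, 5),), gru_input_size=3,
                             gru_hidden_size=4, n_gru_units=2, epochs=2,
                             seed=0).fit(X, y)
        m.save(tmp_path / "cnn.npz")
        back = CNNGRUClassifier.load(tmp_path / "cnn.npz")
        np.testing.assert_array_equal(m.predict_proba(X[:5]),
                                      back.predict_proba(X[:5]))
        assert len(m.training_log()) == 2
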