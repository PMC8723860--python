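"""RBM energy model and DBN training, checked against exhaustive
enumeration of the Boltzmann joint distribution."""

import itertools

import numpy as np
import pytest

from edlcdss import (
    DBNClassifier,
    RBMParams,
    cd_update,
    dbn_feature_vector,
    rbm_energy,
    rbm_hidden_given_visible,
    rbm_visible_given_hidden,
)
from scipy.special import expit as sigmoid


def enumerate_joint(p: RBMParams):
    """Exact joint P(v, h) over all binary states by brute-force
    enumeration of exp(-E) / Z."""
    n_v, n_h = p.a.size, p.b.size
    states_v = list(itertools.product([0, 1], repeat=n_v))
    states_h = list(itertools.product([0, 1], repeat=n_h))
    energy = np.array([
        [rbm_energy(np.array(v, float), np.array(h, float), p)
         for h in states_h] for v in states_v
    ])
    unnorm = np.exp(-energy)
    Z = unnorm.sum()
    return states_v, states_h, unnorm / Z, Z


def random_rbm(n_v, n_h, rng):
    return RBMParams(
        w=rng.normal(0, 1, size=(n_v, n_h)),
        a=rng.normal(0, 1, size=n_v),
        b=rng.normal(0, 1, size=n_h),
    )


class TestEnergy:
    def test_all_zero_state_has_zero_energy(self):
        p = RBMParams(w=np.ones((2, 3)), a=np.ones(2), b=np.ones(3))
        assert rbm_energy(np.zeros(2), np.zeros(3), p) == 0.0

    def test_hand_evaluated_scalar_case(self):
        p = RBMParams(w=[[3.0]], a=[1.0], b=[2.0])
        assert rbm_energy(np.ones(1), np.ones(1), p) == -6.0

    def test_negating_weights_flips_only_interaction(self):
        rng = np.random.default_rng(0)
        p = random_rbm(3, 2, rng)
        v, h = np.array([1.0, 0, 1]), np.array([1.0, 1])
        p_neg = RBMParams(-p.w, p.a, p.b)
        interaction = -(v @ p.w @ h)
        assert rbm_energy(v, h, p_neg) - rbm_energy(v, h, p) == pytest.approx(
            -2 * interaction
        )


class TestConditionals:
    def test_zero_parameters_give_half(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_array_equal(
            rbm_hidden_given_visible(np.ones(3), p), 0.5
        )
        np.testing.assert_array_equal(
            rbm_visible_given_hidden(np.ones(2), p), 0.5
        )

    def test_large_bias_saturates(self):
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.array([30.0]))
        assert rbm_hidden_given_visible(np.zeros(1), p)[0] == pytest.approx(
            1.0, abs=1e-12
        )

    @pytest.mark.parametrize("n_v,n_h", [(2, 2), (3, 2), (1, 5), (4, 2)])
    def test_conditionals_match_bayes_enumeration(self, n_v, n_h):
        rng = np.random.default_rng(n_v * 10 + n_h)
        for _ in range(5):
            p = random_rbm(n_v, n_h, rng)
            states_v, states_h, joint, Z = enumerate_joint(p)
            assert Z > 0
            assert joint.sum() == pytest.approx(1.0, abs=1e-12)
            for vi, v in enumerate(states_v):
                pv = joint[vi].sum()
                for j in range(n_h):
                    marg = sum(joint[vi, hi] for hi, h in enumerate(states_h)
                               if h[j] == 1)
                    expected = marg / pv
                    got = rbm_hidden_given_visible(np.array(v, float), p)[j]
                    assert got == pytest.approx(expected, abs=1e-10)
            for hi, h in enumerate(states_h):
                ph = joint[:, hi].sum()
                for i in range(n_v):
                    marg = sum(joint[vi, hi] for vi, v in enumerate(states_v)
                               if v[i] == 1)
                    got = rbm_visible_given_hidden(np.array(h, float), p)[i]
                    assert got == pytest.approx(marg / ph, abs=1e-10)


class TestContrastiveDivergence:
    def test_zero_learning_rate_is_identity(self, rng):
        p = random_rbm(3, 2, rng)
        batch = rng.random((8, 3))
        q = cd_update(p, batch, lr=0.0, rng=rng)
        np.testing.assert_array_equal(q.w, p.w)
        np.testing.assert_array_equal(q.a, p.a)
        np.testing.assert_array_equal(q.b, p.b)

    def test_expected_update_aligns_with_exact_gradient(self):
        """Mean CD-1 weight update over many seeds has positive inner
        product with the exact log-likelihood gradient (enumeration)."""
        rng = np.random.default_rng(1)
        p = random_rbm(2, 2, rng)
        batch = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
        # exact gradient: E_data[v h^T] - E_model[v h^T]
        states_v, states_h, joint, _ = enumerate_joint(p)
        model_vh = sum(
            joint[vi, hi] * np.outer(v, h)
            for vi, v in enumerate(states_v)
            for hi, h in enumerate(states_h)
        )
        ph = rbm_hidden_given_visible(batch, p)
        data_vh = batch.T @ ph / len(batch)
        exact = data_vh - model_vh
        updates = np.zeros_like(p.w)
        n_rep = 10_000
        for s in range(n_rep):
            q = cd_update(p, batch, lr=1.0, rng=np.random.default_rng(s))
            updates += q.w - p.w
        mean_update = updates / n_rep
        assert np.sum(mean_update * exact) > 0

    def test_reconstruction_error_trends_down(self):
        pattern = np.array([[1.0, 0.0, 1.0, 0.0]])
        finals, initials = [], []
        for s in range(5):
            rng = np.random.default_rng(s)
            p = random_rbm(4, 3, rng)
            def recon_err(q):
                v = rbm_visible_given_hidden(
                    rbm_hidden_given_visible(pattern, q), q
                )
                return float(np.mean((pattern - v) ** 2))
            initials.append(recon_err(p))
            for _ in range(200):
                p = cd_update(p, pattern, lr=0.5, rng=rng)
            finals.append(recon_err(p))
        assert np.median(finals) < np.median(initials)


class TestDBNTraining:
    def test_separable_fixture_training_accuracy(self, separable_Xy):
        X, y = separable_Xy
        m = DBNClassifier(hidden_sizes=(16, 8), epochs_pretrain=5,
                          epochs_finetune=30, seed=0).fit(X, y)
        assert np.mean(m.predict(X) == y) >= 0.95

    def test_frozen_features_head_beats_majority(self, separable_Xy):
        X, y = separable_Xy
        m = DBNClassifier(hidden_sizes=(16, 8), epochs_pretrain=5,
                          epochs_finetune=0, seed=0).fit(X, y)
        majority = max(np.mean(y == c) for c in np.unique(y))
        assert np.mean(m.predict(X) == y) >= majority

    def test_fixed_seed_bit_identical(self, separable_Xy):
        X, y = separable_Xy
        a = DBNClassifier(hidden_sizes=(8,), epochs_pretrain=3,
                          epochs_finetune=3, seed=5).fit(X, y)
        b = DBNClassifier(hidden_sizes=(8,), epochs_pretrain=3,
                          epochs_finetune=3, seed=5).fit(X, y)
        np.testing.assert_array_equal(a.layers_[0].w, b.layers_[0].w)
        np.testing.assert_array_equal(a.head_w_, b.head_w_)

    def test_out_of_range_inputs_rejected(self, rng):
        X = rng.normal(size=(20, 3)) * 10
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            DBNClassifier().fit(X, y)

    def test_feature_vector_layout_and_manual_forward(self, separable_Xy):
        X, y = separable_Xy
        m = DBNClassifier(hidden_sizes=(6, 4), epochs_pretrain=2,
                          epochs_finetune=2, seed=0).fit(X, y)
        fv = dbn_feature_vector(m, X[0])
        assert fv.shape == (4 + 2,)
        # manual layer-by-layer forward pass
        h1 = sigmoid(m.layers_[0].b + X[0] @ m.layers_[0].w)
        h2 = sigmoid(m.layers_[1].b + h1 @ m.layers_[1].w)
        logits = h2 @ m.head_w_ + m.head_b_
        post = np.exp(logits - logits.max())
        post /= post.sum()
        np.testing.assert_allclose(fv, np.concatenate([h2, post]), atol=1e-12)
        np.testing.assert_allclose(post.sum(), 1.0)

    def test_small_lr_finetuning_does_not_blow_up_loss(self, separable_Xy):
        X, y = separable_Xy
        m = DBNClassifier(hidden_sizes=(8,), epochs_pretrain=2,
                          epochs_finetune=10, lr_finetune=1e-3, seed=0)
        m.fit(X, y)
        losses = m.finetune_losses_
        assert losses[-1] <= losses[0] + 1e-3


class TestPersistence:
    def test_archive_round_trip(self, tmp_path, separable_Xy):
        X, y = separable_Xy
        m = DBNClassifier(hidden_sizes=(8, 4), epochs_pretrain=2,
                          epochs_finetune=2, seed=0).fit(X, y)
        m.save(tmp_path / "dbn.npz")
        back = DBNClassifier.load(tmp_path / "dbn.npz")
        np.testing.assert_array_equal(m.predict_proba(X[:5]),
                                      back.predict_proba(X[:5]))

    def test_training_log_shape(self, separable_Xy):
        X, y = separable_Xy
        m = DBNClassifier(hidden_sizes=(8,), epochs_pretrain=3,
                          epochs_finetune=4, seed=0).fit(X, y)
        log = m.training_log()
        assert list(log.columns) == ["phase", "epoch", "value"]
        assert (log["phase"] == "finetune").sum() == 4
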