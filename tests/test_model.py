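"""Losses, training, prediction, and the KAE ablation."""

import numpy as np
import pytest

from helpers import companion_series, delay_states, identity_mlp_weights

from ekatp.koopman import fit_companion_lsq, materialize, CompanionForward, inverse_companion
from ekatp.model import (
    ConstraintViolationError,
    DecoderSpec,
    EKATPModel,
    EncoderSpec,
    LossReport,
    LossWeights,
    TrainConfig,
    loss_bwd,
    loss_con,
    loss_fwd,
    loss_id,
    loss_idy,
    make_kae,
    predict,
    total_loss,
    train,
)


class TestLossId:
    def test_identity_is_zero(self):
        f = np.array([1.0, 2.0, 3.0])
        assert loss_id(f, f) == 0.0

    def test_hand_arithmetic(self):
        assert loss_id(np.array([1.0, 4.0]), np.array([1.0, 2.0])) == pytest.approx(2.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(6)
        r = rng.standard_normal(6)
        assert loss_id(f + 3 * r, f) == pytest.approx(9 * loss_id(f + r, f))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_id(np.ones(3), np.ones(4))


class TestZeroLossOracle:
    """Master oracle: the hand-built exact configuration zeroes every term."""

    @pytest.mark.parametrize("k", [1, 3])
    def test_all_five_losses_vanish(self, exact_model, companion_ambient, k):
        mid = companion_ambient.shape[1] // 2
        window = companion_ambient[:, mid - k: mid + k + 1]
        rec = exact_model.decode(exact_model.encode(window[:, k]))
        assert loss_id(rec, window[:, k]) < 1e-10
        assert loss_fwd(exact_model, window, k) < 1e-10
        assert loss_bwd(exact_model, window, k) < 1e-10
        assert loss_idy(exact_model, window, k) < 1e-10
        assert loss_con(exact_model, window, k) < 1e-10


class TestHandUnrolledLosses:
    """k=1, L=n=2, identity autoencoder: every loss against explicit arithmetic."""

    @pytest.fixture
    def toy(self):
        enc = EncoderSpec(2, 2, hidden=(2,), activation="identity")
        model = EKATPModel(enc, DecoderSpec.mirror(enc), seed=0)
        identity_mlp_weights(model.encoder, 2)
        identity_mlp_weights(model.decoder, 2)
        model.a.data = np.array([0.3, 0.6])
        model.b.data = np.array([0.2, -0.4])
        window = np.array([[1.0, 2.0, -1.0], [0.5, -0.5, 2.0]])  # F_{t-1}, F_t, F_{t+1}
        return model, window

    def test_forward(self, toy):
        model, w = toy
        C = materialize(CompanionForward(model.a.data))
        pred = C @ w[:, 1]
        expected = np.mean((pred - w[:, 2]) ** 2)
        assert loss_fwd(model, w, 1) == pytest.approx(expected, abs=1e-12)

    def test_backward(self, toy):
        model, w = toy
        D = np.array([[0.2, -0.4], [1.0, 0.0]])
        pred = D @ w[:, 1]
        expected = np.mean((pred - w[:, 0]) ** 2)
        assert loss_bwd(model, w, 1) == pytest.approx(expected, abs=1e-12)

    def test_latent_linearity(self, toy):
        model, w = toy
        C = materialize(CompanionForward(model.a.data))
        D = np.array([[0.2, -0.4], [1.0, 0.0]])
        expected = np.mean((C @ w[:, 1] - w[:, 2]) ** 2) + np.mean((D @ w[:, 1] - w[:, 0]) ** 2)
        assert loss_idy(model, w, 1) == pytest.approx(expected, abs=1e-12)

    def test_consistency(self, toy):
        model, w = toy
        C = materialize(CompanionForward(model.a.data))
        D = np.array([[0.2, -0.4], [1.0, 0.0]])
        y = w[:, 1]
        expected = np.mean((D @ C @ y - y) ** 2) + np.mean((C @ D @ y - y) ** 2)
        assert loss_con(model, w, 1) == pytest.approx(expected, abs=1e-12)

    def test_consistency_symmetric_when_operators_commute(self, toy):
        model, w = toy
        fwd = CompanionForward(model.a.data)
        model.b.data = inverse_companion(fwd).b  # D = C^{-1} commutes with C
        C = materialize(fwd)
        D = np.linalg.inv(C)
        y = w[:, 1]
        s1 = np.mean((D @ C @ y - y) ** 2)
        s2 = np.mean((C @ D @ y - y) ** 2)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert loss_con(model, w, 1) < 1e-20

    def test_window_too_short_rejected(self, toy):
        model, w = toy
        with pytest.raises(ValueError):
            loss_fwd(model, w, 2)


class TestTotalLoss:
    def test_unit_case(self):
        report = LossReport(1, 1, 1, 1, 1, 0)
        assert total_loss(report, LossWeights()) == pytest.approx(5.0)

    def test_hand_arithmetic(self):
        report = LossReport(2, 3, 1, 4, 2, 0)
        w = LossWeights(0.1, 1, 1, 0.5, 0.5)
        assert total_loss(report, w) == pytest.approx(7.2)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(-1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0, 0, 0)

    def test_zero_weight_masks_gradient(self):
        # with lambda_fwd = 0 the operator coefficients receive no gradient
        # from the forward term alone (id/idy/con terms removed too)
        enc = EncoderSpec(3, 2, hidden=(4,))
        model = EKATPModel(enc, weights=LossWeights(1, 0, 0, 0, 0), seed=0)
        rng = np.random.default_rng(0)
        W = rng.standard_normal((2, 5, 3))
        losses = model._batch_losses(W, 2)
        total = model._weighted_total(losses)
        for p in model.params:
            p.grad = None
        total.backward()
        assert model.a.grad is None or np.allclose(model.a.grad, 0)

    def test_report_total_is_exact_weighted_sum(self, exact_model, companion_ambient):
        cfg = TrainConfig(k=2, epochs=1, train_range=(0, 40), seed=0, normalize=False)
        hist = train(exact_model, companion_ambient, cfg)
        h = hist[-1]
        assert h.total == pytest.approx(total_loss(h, exact_model.weights), abs=1e-10)


class TestEncodeDecode:
    def test_batch_order_preserved(self):
        enc = EncoderSpec(4, 3, hidden=(8,))
        model = EKATPModel(enc, seed=1)
        rng = np.random.default_rng(2)
        F = rng.standard_normal((4, 6))
        batch = model.encode(F)
        singles = np.stack([model.encode(F[:, i]) for i in range(6)], axis=1)
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_nan_input_rejected(self):
        model = EKATPModel(EncoderSpec(3, 2, hidden=(4,)), seed=0)
        bad = np.array([1.0, np.nan, 0.0])
        with pytest.raises(ValueError):
            model.encode(bad)

    def test_dimension_checked(self):
        model = EKATPModel(EncoderSpec(3, 2, hidden=(4,)), seed=0)
        with pytest.raises(ValueError):
            model.encode(np.ones(5))
        with pytest.raises(ValueError):
            model.decode(np.ones(5))


class TestTraining:
    def _latent_linear_data(self, a_true, T=260):
        y = companion_series(a_true, np.array([0.5, -1.0, 0.8, 0.3]), T)
        return delay_states(y, 4).T  # identity lift, n = L = 4

    def test_loss_decreases(self, stable_companion):
        data = self._latent_linear_data(stable_companion.a)
        enc = EncoderSpec(4, 4, hidden=(8,), activation="identity")
        model = EKATPModel(enc, seed=0)
        hist = train(model, data, TrainConfig(k=3, epochs=30, train_range=(0, 200), seed=0))
        assert hist[-1].total <= hist[0].total

    def test_determinism(self, stable_companion):
        data = self._latent_linear_data(stable_companion.a)
        cfg = TrainConfig(k=2, epochs=5, train_range=(0, 150), seed=42)
        finals = []
        for _ in range(2):
            model = EKATPModel(EncoderSpec(4, 3, hidden=(6,)), seed=7)
            train(model, data, cfg)
            finals.append(np.concatenate([p.data.ravel() for p in model.params]))
        np.testing.assert_array_equal(finals[0], finals[1])

    def test_companion_recovery_matches_lsq(self, stable_companion):
        """Gradient training on companion-generated data recovers the
        generator coefficients, agreeing with the least-squares oracle."""
        a_true = stable_companion.a
        data = self._latent_linear_data(a_true)
        enc = EncoderSpec(4, 4, hidden=(4,), activation="identity")
        model = EKATPModel(enc, seed=1)
        train(model, data, TrainConfig(k=3, epochs=600, lr=1e-2,
                                       train_range=(0, 250), seed=1))
        lsq = fit_companion_lsq(delay_states(
            companion_series(a_true, np.array([0.5, -1.0, 0.8, 0.3]), 100), 4))
        np.testing.assert_allclose(lsq.a, a_true, atol=1e-8)
        np.testing.assert_allclose(model.a.data, a_true, atol=1e-2)

    def test_constraint_violation_abort_mode(self, stable_companion):
        data = self._latent_linear_data(stable_companion.a)
        model = EKATPModel(EncoderSpec(4, 3, hidden=(4,)), seed=0)
        model.a.data[0] = 0.0  # violate a1 != 0; lr = 0 keeps it pinned
        with pytest.raises(ConstraintViolationError):
            train(model, data, TrainConfig(k=2, epochs=1, lr=0.0, train_range=(0, 100),
                                           seed=0, constraint_mode="abort"))

    def test_constraint_clamped_by_default(self, stable_companion):
        data = self._latent_linear_data(stable_companion.a)
        model = EKATPModel(EncoderSpec(4, 3, hidden=(4,)), seed=0)
        model.a.data[0] = 0.0
        model.b.data[-1] = 0.0
        train(model, data, TrainConfig(k=2, epochs=1, lr=0.0, train_range=(0, 100), seed=0))
        assert abs(model.a.data[0]) >= model._CONSTRAINT_FLOOR
        assert abs(model.b.data[-1]) >= model._CONSTRAINT_FLOOR

    def test_short_segment_rejected(self):
        model = EKATPModel(EncoderSpec(4, 3, hidden=(4,)), seed=0)
        with pytest.raises(ValueError):
            train(model, np.ones((4, 30)), TrainConfig(k=8, epochs=1, train_range=(0, 10)))


class TestPredict:
    def test_horizon_zero_is_reconstruction(self, exact_model, companion_ambient):
        exact_model.trained = True
        f = companion_ambient[:, 5]
        out = predict(exact_model, f, 0)
        np.testing.assert_allclose(out[:, 0], f, atol=1e-10)

    def test_exact_model_predicts_forward(self, exact_model, companion_ambient):
        exact_model.trained = True
        pred = predict(exact_model, companion_ambient[:, 10], 5)
        np.testing.assert_allclose(pred, companion_ambient[:, 11:16], atol=1e-8)

    def test_forward_backward_round_trip(self, exact_model, companion_ambient):
        exact_model.trained = True
        f = companion_ambient[:, 20]
        fwd = predict(exact_model, f, 4, "forward")
        back = predict(exact_model, fwd[:, -1], 4, "backward")
        np.testing.assert_allclose(back[:, -1], f, atol=1e-8)

    def test_fifty_step_block_in_ambient_dims(self):
        # the genomics protocol decodes a 96 x 50 forecast block
        model = EKATPModel(EncoderSpec(96, 8, hidden=(16,)), seed=0)
        model.trained = True
        out = predict(model, np.zeros(96), 50)
        assert out.shape == (96, 50)

    def test_untrained_model_warns(self):
        model = EKATPModel(EncoderSpec(3, 2, hidden=(4,)), seed=0)
        with pytest.warns(UserWarning):
            predict(model, np.zeros(3), 1)


class TestKAE:
    def test_parameter_count(self):
        enc = EncoderSpec(6, 4, hidden=(8,))
        ekatp_ops = EKATPModel(enc, seed=0)
        kae = make_kae(enc, seed=0)
        assert kae.K.data.size == 16  # L^2 dense entries
        assert ekatp_ops.a.data.size + ekatp_ops.b.data.size == 8  # 2L structured

    def test_backward_terms_removed(self):
        kae = make_kae(EncoderSpec(4, 3, hidden=(4,)), seed=0)
        assert kae.weights.lambda_bwd == 0.0
        assert kae.weights.lambda_con == 0.0
        rng = np.random.default_rng(0)
        W = rng.standard_normal((2, 5, 4))
        losses = kae._batch_losses(W, 2)
        assert float(losses["l_bwd"].data) == 0.0
        assert float(losses["l_con"].data) == 0.0

    def test_kae_drives_losses_down_on_latent_linear_data(self, stable_companion):
        y = companion_series(stable_companion.a, np.array([0.5, -1.0, 0.8, 0.3]), 200)
        data = delay_states(y, 4).T
        kae = make_kae(EncoderSpec(4, 4, hidden=(4,), activation="identity"), seed=2)
        hist = train(kae, data, TrainConfig(k=3, epochs=300, lr=1e-2,
                                            train_range=(0, 180), seed=2))
        assert hist[-1].l_fwd < 1e-3

    def test_backward_prediction_unsupported(self):
        kae = make_kae(EncoderSpec(4, 3, hidden=(4,)), seed=0)
        kae.trained = True
        with pytest.raises(ValueError):
            predict(kae, np.zeros(4), 2, "backward")


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        for build in (
            lambda: EKATPModel(EncoderSpec(3, 3, hidden=(5,)), seed=1),
            lambda: make_kae(EncoderSpec(3, 3, hidden=(5,)), seed=1),
        ):
            model = build()
            W = rng.standard_normal((2, 5, 3))

            def total():
                return model._weighted_total(model._batch_losses(W, 2))

            t = total()
            for p in model.params:
                p.grad = None
            t.backward()
            h = 1e-4
            for p in model.params:
                flat = p.data.reshape(-1)
                for idx in range(0, flat.size, max(1, flat.size // 4)):
                    orig = flat[idx]
                    flat[idx] = orig + h
                    lp = float(total().data)
                    flat[idx] = orig - h
                    lm = float(total().data)
                    flat[idx] = orig
                    fd = (lp - lm) / (2 * h)
                    g = p.grad.reshape(-1)[idx]
                    assert abs(fd - g) <= 1e-4 * max(1.0, abs(fd))


def test_save_load_round_trip(tmp_path, exact_model, companion_ambient):
    exact_model.trained = True
    path = tmp_path / "model.json"
    exact_model.save(path)
    loaded = EKATPModel.load(path)
    f = companion_ambient[:, 3]
    np.testing.assert_allclose(loaded.encode(f), exact_model.encode(f), atol=0)
    np.testing.assert_array_equal(loaded.a.data, exact_model.a.data)
    assert loaded.trained
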