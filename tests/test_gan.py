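import numpy as np
import pytest

from mitgan.dataset import Normalization, SampleSet
from mitgan.forward import MeasurementFrame
from mitgan.gan import (
    NetworkSpec,
    TrainConfig,
    _backward_full,
    _forward_cached,
    forward_pass,
    init_params,
    load_checkpoint,
    optimal_discriminator,
    pretrain_generator,
    reconstruct,
    save_checkpoint,
    train_gan,
)
from mitgan.geometry import build_grid


def _numeric_grad(loss, params, eps=1e-6):
    """Central-difference gradient of a scalar loss over (W, b) pairs."""
    out = []
    for li, (W, b) in enumerate(params):
        gW = np.zeros_like(W)
        for idx in np.ndindex(W.shape):
            p_plus = [(w.copy(), bb.copy()) for w, bb in params]
            p_plus[li][0][idx] += eps
            p_minus = [(w.copy(), bb.copy()) for w, bb in params]
            p_minus[li][0][idx] -= eps
            gW[idx] = (loss(p_plus) - loss(p_minus)) / (2 * eps)
        gb = np.zeros_like(b)
        for idx in np.ndindex(b.shape):
            p_plus = [(w.copy(), bb.copy()) for w, bb in params]
            p_plus[li][1][idx] += eps
            p_minus = [(w.copy(), bb.copy()) for w, bb in params]
            p_minus[li][1][idx] -= eps
            gb[idx] = (loss(p_plus) - loss(p_minus)) / (2 * eps)
        out.append((gW, gb))
    return out


def _assert_grads_close(analytic, numeric, rtol=1e-4):
    for (aW, ab), (nW, nb) in zip(analytic, numeric):
        scale = max(np.abs(nW).max(), 1e-8)
        np.testing.assert_allclose(aW, nW, atol=rtol * scale)
        scale = max(np.abs(nb).max(), 1e-8)
        np.testing.assert_allclose(ab, nb, atol=rtol * scale)


class TestForwardPass:
    def test_zero_parameters_sigmoid_gives_half(self):
        spec = NetworkSpec((3, 4), ("sigmoid",))
        params = [(np.zeros((4, 3)), np.zeros(4))]
        np.testing.assert_array_equal(forward_pass(spec, params, np.ones(3)), 0.5)

    def test_identity_linear_layer(self):
        spec = NetworkSpec((3, 3), ("linear",))
        params = [(np.eye(3), np.zeros(3))]
        x = np.array([0.3, -1.2, 4.0])
        np.testing.assert_array_equal(forward_pass(spec, params, x), x)

    def test_two_layer_net_matches_hand_computation(self):
        spec = NetworkSpec((2, 2, 1), ("tanh", "sigmoid"))
        W1 = np.array([[1.0, -1.0], [0.5, 0.5]])
        b1 = np.array([0.0, 0.1])
        W2 = np.array([[2.0, -1.0]])
        b2 = np.array([0.2])
        x = np.array([0.4, 0.6])
        h = np.tanh(W1 @ x + b1)
        expected = 1.0 / (1.0 + np.exp(-(W2 @ h + b2)))
        got = forward_pass(spec, [(W1, b1), (W2, b2)], x)
        np.testing.assert_allclose(got, expected, rtol=1e-15)

    def test_shape_mismatch_rejected(self):
        spec = NetworkSpec((3, 2), ("relu",))
        with pytest.raises(ValueError):
            forward_pass(spec, init_params(spec), np.ones(5))

    def test_mismatched_spec_lengths_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec((3, 4, 2), ("relu",))


class TestGradientCorrectness:
    """Finite-difference checks of both training losses on tiny networks."""

    def test_l2_loss_gradient(self, rng):
        spec = NetworkSpec((3, 4, 2), ("tanh", "sigmoid"), init_seed=3)
        params = init_params(spec)
        X = rng.normal(size=(5, 3))
        Y = rng.uniform(size=(5, 2))

        def loss(p):
            out = forward_pass(spec, p, X)
            return float(np.mean(np.sum((out - Y) ** 2, axis=1)))

        zs, acts = _forward_cached(spec, params, X)
        analytic, _ = _backward_full(spec, params, zs, acts, 2 * (acts[-1] - Y) / 5)
        _assert_grads_close(analytic, _numeric_grad(loss, params))

    def test_discriminator_value_gradient(self, rng):
        spec = NetworkSpec((2, 4, 1), ("leaky_relu", "sigmoid"), init_seed=5)
        params = init_params(spec)
        real = rng.normal(size=(4, 2))
        fake = rng.normal(size=(4, 2))

        def neg_value(p):
            dr = forward_pass(spec, p, real).ravel()
            df = forward_pass(spec, p, fake).ravel()
            return float(-np.mean(np.log(dr) + np.log(1 - df)))

        zs_r, acts_r = _forward_cached(spec, params, real)
        zs_f, acts_f = _forward_cached(spec, params, fake)
        g_r, _ = _backward_full(spec, params, zs_r, acts_r, -(1 - acts_r[-1]) / 4, wrt="preact")
        g_f, _ = _backward_full(spec, params, zs_f, acts_f, acts_f[-1] / 4, wrt="preact")
        analytic = [(a[0] + b[0], a[1] + b[1]) for a, b in zip(g_r, g_f)]
        _assert_grads_close(analytic, _numeric_grad(neg_value, params))

    def test_generator_adversarial_gradient_through_discriminator(self, rng):
        gspec = NetworkSpec((2, 3, 2), ("tanh", "sigmoid"), init_seed=1)
        dspec = NetworkSpec((2, 3, 1), ("leaky_relu", "sigmoid"), init_seed=2)
        gp, dp = init_params(gspec), init_params(dspec)
        V = rng.normal(size=(6, 2))

        def gen_loss(p):
            fake = forward_pass(gspec, p, V)
            df = forward_pass(dspec, dp, fake).ravel()
            return float(np.mean(np.log(1 - df)))

        zs_g, acts_g = _forward_cached(gspec, gp, V)
        zs_d, acts_d = _forward_cached(dspec, dp, acts_g[-1])
        _, grad_img = _backward_full(dspec, dp, zs_d, acts_d, -acts_d[-1] / 6, wrt="preact")
        analytic, _ = _backward_full(gspec, gp, zs_g, acts_g, grad_img)
        _assert_grads_close(analytic, _numeric_grad(gen_loss, gp))


class TestOptimalDiscriminator:
    def test_equal_densities_give_half(self):
        assert optimal_discriminator(0.3, 0.3) == pytest.approx(0.5)
        np.testing.assert_allclose(optimal_discriminator([1.0, 2.0], [1.0, 2.0]), 0.5)

    def test_vanishing_generator_density_gives_one(self):
        assert optimal_discriminator(0.7, 0.0) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert optimal_discriminator(0.2, 0.6) == pytest.approx(0.25)

    def test_both_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            optimal_discriminator([0.0], [0.0])

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            optimal_discriminator(-0.1, 0.5)


def _toy_set(n, seed, grid):
    rng = np.random.default_rng(seed)
    V = rng.normal(size=(n, 1))
    Y = 1 / (1 + np.exp(-1.7 * V)) * 0.8 + 0.1
    return SampleSet(V, Y, grid, 0.25)


class TestPretrainGenerator:
    def test_loss_decreases(self, small_grid):
        sset = _toy_set(100, 0, small_grid)
        cfg = TrainConfig(pretrain_epochs=30, pretrain_batch=20, learning_rate=1e-2, seed=0)
        spec = NetworkSpec((1, 6, 1), ("tanh", "sigmoid"), init_seed=0)
        state = pretrain_generator(spec, sset, cfg)
        hist = state.history["pretrain_loss"]
        assert hist[-1] < hist[0]

    def test_memorizes_tiny_set(self, small_grid):
        sset = _toy_set(10, 1, small_grid)
        cfg = TrainConfig(pretrain_epochs=800, pretrain_batch=10, learning_rate=1e-2,
                          l2_coeff=0.0, seed=0)
        spec = NetworkSpec((1, 16, 1), ("tanh", "sigmoid"), init_seed=0)
        state = pretrain_generator(spec, sset, cfg)
        pred = forward_pass(spec, state.gen_params, sset.voltages)
        assert np.mean((pred - sset.conductivities) ** 2) < 1e-3

    def test_outputs_within_sigmoid_range(self, small_grid):
        sset = _toy_set(50, 2, small_grid)
        cfg = TrainConfig(pretrain_epochs=5, pretrain_batch=25, seed=0)
        spec = NetworkSpec((1, 4, 1), ("relu", "sigmoid"), init_seed=0)
        state = pretrain_generator(spec, sset, cfg)
        pred = forward_pass(spec, state.gen_params, sset.voltages)
        assert np.all((pred > 0) & (pred < 1))

    def test_seeded_runs_reproduce_histories(self, small_grid):
        sset = _toy_set(60, 3, small_grid)
        cfg = TrainConfig(pretrain_epochs=10, pretrain_batch=20, seed=4)
        spec = NetworkSpec((1, 5, 1), ("tanh", "sigmoid"), init_seed=4)
        h1 = pretrain_generator(spec, sset, cfg).history["pretrain_loss"]
        h2 = pretrain_generator(spec, sset, cfg).history["pretrain_loss"]
        assert h1 == h2

    def test_empty_set_rejected(self, small_grid):
        empty = SampleSet(np.empty((0, 1)), np.empty((0, small_grid.active_count)),
                          small_grid, 0.25)
        spec = NetworkSpec((1, 2, small_grid.active_count), ("tanh", "sigmoid"))
        with pytest.raises(ValueError):
            pretrain_generator(spec, empty, TrainConfig(seed=0))


@pytest.fixture(scope="module")
def toy_grid():
    return build_grid(1, 0.1)


class TestTrainGan:
    def test_discriminator_near_half_at_convergence(self, toy_grid):
        sset = _toy_set(2000, 42, toy_grid)
        val = SampleSet(sset.voltages[:200], sset.conductivities[:200], toy_grid, 0.25)
        gspec = NetworkSpec((1, 8, 1), ("tanh", "sigmoid"), init_seed=0)
        dspec = NetworkSpec((1, 16, 1), ("leaky_relu", "sigmoid"), init_seed=1)
        cfg = TrainConfig(pretrain_epochs=200, pretrain_batch=100, gan_epochs=30,
                          gan_batch=200, learning_rate=1e-2, l2_coeff=0.0, seed=0)
        pre = pretrain_generator(gspec, sset, cfg)
        state = train_gan(pre, dspec, sset, val, cfg)
        d_real = forward_pass(dspec, state.disc_params, sset.conductivities).ravel()
        assert abs(d_real.mean() - 0.5) < 0.1

    def test_stopping_rule_fires_with_perfect_generator(self, toy_grid):
        sset = _toy_set(400, 7, toy_grid)
        val = SampleSet(sset.voltages[:50], sset.conductivities[:50], toy_grid, 0.25)
        gspec = NetworkSpec((1, 12, 1), ("tanh", "sigmoid"), init_seed=0)
        dspec = NetworkSpec((1, 8, 1), ("leaky_relu", "sigmoid"), init_seed=1)
        cfg = TrainConfig(pretrain_epochs=500, pretrain_batch=50, gan_epochs=50,
                          gan_batch=100, learning_rate=1e-2, l2_coeff=0.0, seed=0)
        pre = pretrain_generator(gspec, sset, cfg)
        state = train_gan(pre, dspec, sset, val, cfg)
        assert state.stop_reason == "converged"
        assert len(state.history["gen_loss"]) < cfg.gan_epochs

    def test_finetuning_does_not_degrade_validation_mse(self, toy_grid):
        sset = _toy_set(500, 8, toy_grid)
        val = SampleSet(sset.voltages[:80], sset.conductivities[:80], toy_grid, 0.25)
        gspec = NetworkSpec((1, 8, 1), ("tanh", "sigmoid"), init_seed=0)
        dspec = NetworkSpec((1, 8, 1), ("leaky_relu", "sigmoid"), init_seed=1)
        cfg = TrainConfig(pretrain_epochs=100, pretrain_batch=50, gan_epochs=10,
                          gan_batch=100, learning_rate=1e-3, seed=0)
        pre = pretrain_generator(gspec, sset, cfg)
        pre_mse = np.mean(
            (forward_pass(gspec, pre.gen_params, val.voltages) - val.conductivities) ** 2
        )
        state = train_gan(pre, dspec, sset, val, cfg)
        post_mse = np.mean(
            (forward_pass(gspec, state.gen_params, val.voltages) - val.conductivities) ** 2
        )
        assert post_mse <= 1.2 * pre_mse

    def test_seeded_reproducibility_of_histories(self, toy_grid):
        sset = _toy_set(300, 9, toy_grid)
        val = SampleSet(sset.voltages[:40], sset.conductivities[:40], toy_grid, 0.25)
        gspec = NetworkSpec((1, 6, 1), ("tanh", "sigmoid"), init_seed=0)
        dspec = NetworkSpec((1, 6, 1), ("leaky_relu", "sigmoid"), init_seed=1)
        cfg = TrainConfig(pretrain_epochs=20, pretrain_batch=50, gan_epochs=5,
                          gan_batch=100, seed=3)
        runs = [
            train_gan(pretrain_generator(gspec, sset, cfg), dspec, sset, val, cfg).history
            for _ in range(2)
        ]
        assert runs[0]["gen_loss"] == runs[1]["gen_loss"]
        assert runs[0]["val_mse"] == runs[1]["val_mse"]


class TestReconstructAndCheckpoints:
    def test_reconstruct_shape_range_and_determinism(self, small_grid):
        spec = NetworkSpec((56, 8, small_grid.active_count), ("tanh", "sigmoid"), init_seed=0)
        from mitgan.gan import TrainState

        state = TrainState(spec, init_params(spec))
        norm = Normalization(-1.0, 1.0, 0.05, 0.25)
        frame = MeasurementFrame(np.linspace(-0.5, 0.5, 56))
        ph1 = reconstruct(state, frame, norm, small_grid)
        ph2 = reconstruct(state, frame, norm, small_grid)
        assert ph1.values.shape == (small_grid.active_count,)
        assert np.all((ph1.values >= 0.05) & (ph1.values <= 0.25))
        np.testing.assert_array_equal(ph1.values, ph2.values)

    def test_missing_normalization_rejected(self, small_grid):
        from mitgan.gan import TrainState

        spec = NetworkSpec((56, 4, small_grid.active_count), ("tanh", "sigmoid"))
        state = TrainState(spec, init_params(spec))
        with pytest.raises(ValueError):
            reconstruct(state, MeasurementFrame(np.zeros(56)), None, small_grid)

    def test_checkpoint_round_trip(self, tmp_path):
        from mitgan.gan import TrainState

        gspec = NetworkSpec((3, 5, 2), ("relu", "sigmoid"), init_seed=0)
        dspec = NetworkSpec((2, 4, 1), ("leaky_relu", "sigmoid"), init_seed=1)
        state = TrainState(gspec, init_params(gspec), dspec, init_params(dspec),
                           history={"val_mse": [0.5, 0.4]}, stop_reason="max_iters")
        save_checkpoint(state, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        assert back.gen_spec == gspec and back.disc_spec == dspec
        assert back.stop_reason == "max_iters"
        assert back.history["val_mse"] == [0.5, 0.4]
        for (W1, b1), (W2, b2) in zip(state.gen_params, back.gen_params):
            np.testing.assert_array_equal(W1, W2)
            np.testing.assert_array_equal(b1, b2)
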