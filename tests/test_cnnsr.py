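"""Three-layer convolutional engine: forward pass, gradients, training."""

import numpy as np
import pytest

from lenssr.cnnsr import (
    CnnConfig,
    _backward,
    _forward,
    _init_model,
    _loss_and_grads,
    apply_cnnsr,
    conv_forward,
    load_cnn,
    save_cnn,
    train_cnn,
)
from lenssr.resample import hf_decompose


def _toy_config(**kw):
    defaults = dict(n1=2, n2=2, f1=5, f2=1, f3=3, eta=0.5, iters=1, seed=0)
    defaults.update(kw)
    return CnnConfig(**defaults)


class TestConvForward:
    def test_zero_filters_give_constant_bias_after_relu(self, rng):
        x = rng.random((1, 6, 6))
        W = np.zeros((3, 1, 3, 3))
        out = conv_forward(x, W, np.array([0.7, -0.2, 0.0]), relu=True)
        np.testing.assert_allclose(out[0], 0.7)
        np.testing.assert_allclose(out[1], 0.0)  # max(0, -0.2)
        np.testing.assert_allclose(out[2], 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        """Direct nested-loop cross-correlation with replicate padding."""
        x = rng.random((1, 4, 4))
        W = rng.normal(size=(1, 1, 3, 3))
        b = rng.normal(size=1)
        out = conv_forward(x, W, b)
        for r in range(4):
            for c in range(4):
                acc = b[0]
                for i in range(3):
                    for j in range(3):
                        rr = min(max(r + i - 1, 0), 3)
                        cc = min(max(c + j - 1, 0), 3)
                        acc += W[0, 0, i, j] * x[0, rr, cc]
                assert abs(out[0, r, c] - acc) < 1e-12

    def test_layer_one_produces_n1_feature_maps(self, rng):
        cfg = CnnConfig()
        model = _init_model(cfg)
        out = conv_forward(rng.random((1, 12, 12)), model.W1, model.B1, relu=True)
        assert out.shape == (64, 12, 12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            conv_forward(rng.random((2, 4, 4)), np.zeros((1, 3, 3, 3)), np.zeros(1))


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Central finite differences on a 2-filter toy net, 8x8 input."""
        cfg = _toy_config()
        m = _init_model(cfg)
        # move off the tiny-init saddle so gradients have healthy magnitude
        gen = np.random.default_rng(5)
        for name in ("W1", "B1", "W2", "B2", "W3", "B3"):
            arr = getattr(m, name)
            setattr(m, name, arr + gen.normal(0, 0.3, arr.shape))
        y = [rng.random((8, 8))]
        x = [rng.random((8, 8))]
        border = cfg.loss_border
        _, grads = _loss_and_grads(m, y, x, border)
        eps = 1e-5
        for name in ("W1", "B1", "W2", "B2", "W3", "B3"):
            arr = getattr(m, name)
            flat = arr.reshape(-1)
            idxs = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for k in idxs:
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = _loss_and_grads(m, y, x, border)
                flat[k] = orig - eps
                lm, _ = _loss_and_grads(m, y, x, border)
                flat[k] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name].reshape(-1)[k]
                denom = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / denom < 1e-4, f"{name}[{k}]: fd={fd} an={an}"

    def test_seeded_init_is_bit_identical(self):
        m1, m2 = _init_model(_toy_config(seed=4)), _init_model(_toy_config(seed=4))
        for name in ("W1", "W2", "W3"):
            np.testing.assert_array_equal(getattr(m1, name), getattr(m2, name))
        assert np.all(m1.B1 == 0) and np.all(m1.B3 == 0)


class TestTraining:
    def test_single_pair_overfit_drives_loss_down(self, small_pairs):
        """Momentum SGD on one image: loss falls well below its start.

        Uses the full-width architecture — very narrow nets can lose every
        second-layer ReLU to early negative updates and stall at the
        constant-output plateau.
        """
        m = train_cnn(small_pairs[:1], CnnConfig(iters=2000, seed=1))
        assert m.loss_history[-1] < 0.1 * m.loss_history[0]

    def test_loss_history_recorded_and_finite(self, small_pairs):
        cfg = _toy_config(iters=5)
        m = train_cnn(small_pairs[:1], cfg)
        assert m.loss_history.shape == (5,)
        assert np.all(np.isfinite(m.loss_history))

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_aborts_with_diagnostic(self, small_pairs):
        cfg = _toy_config(n1=8, n2=4, eta=500.0, iters=400, seed=1)
        with pytest.raises(RuntimeError, match="smaller eta"):
            train_cnn(small_pairs[:1], cfg)

    def test_same_seed_reproduces_training_bitwise(self, small_pairs):
        cfg = _toy_config(iters=10)
        m1 = train_cnn(small_pairs[:2], cfg)
        m2 = train_cnn(small_pairs[:2], cfg)
        for name in ("W1", "B1", "W2", "B2", "W3", "B3"):
            np.testing.assert_array_equal(getattr(m1, name), getattr(m2, name))


class TestInference:
    def test_output_size_is_t_times_input(self, rng):
        m = _init_model(_toy_config(t=4))
        assert apply_cnnsr(rng.random((20, 20)), m).shape == (80, 80)

    def test_constant_input_gives_constant_output(self):
        m = _init_model(CnnConfig(n1=4, n2=3, seed=2))
        gen = np.random.default_rng(0)
        for name in ("W1", "B1", "W2", "B2", "W3", "B3"):
            arr = getattr(m, name)
            setattr(m, name, arr + gen.normal(0, 0.2, arr.shape))
        out, _ = _forward(np.full((16, 16), 0.6), m)
        assert np.ptp(out) < 1e-12

    def test_receptive_field_is_49_pixels(self):
        """Perturbing one input pixel reaches exactly a 7x7 = 49-px patch."""
        cfg = CnnConfig(n1=4, n2=3, seed=0)
        m = _init_model(cfg)
        gen = np.random.default_rng(1)
        for name in ("W1", "W2", "W3"):
            arr = getattr(m, name)
            # positive weights keep every ReLU active so influence propagates
            setattr(m, name, np.abs(gen.normal(0.1, 0.05, arr.shape)) + 0.01)
        y = np.full((20, 20), 0.5)
        base, _ = _forward(y, m)
        y2 = y.copy()
        y2[10, 10] += 0.01
        pert, _ = _forward(y2, m)
        changed = np.abs(pert - base) > 1e-13
        assert changed.sum() == 49 == cfg.receptive_field**2
        rows, cols = np.where(changed)
        assert rows.min() == 7 and rows.max() == 13
        assert cols.min() == 7 and cols.max() == 13

    def test_translation_equivariance_away_from_borders(self, rng):
        m = _init_model(CnnConfig(n1=4, n2=3, seed=3))
        gen = np.random.default_rng(2)
        for name in ("W1", "B1", "W2", "B2", "W3", "B3"):
            arr = getattr(m, name)
            setattr(m, name, arr + gen.normal(0, 0.2, arr.shape))
        base = rng.random((24, 24))
        shifted = np.roll(base, 1, axis=1)
        out1, _ = _forward(base, m)
        out2, _ = _forward(shifted, m)
        crop1 = out1[8:-8, 8:-9]
        crop2 = out2[8:-8, 9:-8]
        assert np.abs(crop1 - crop2).max() < 1e-8


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path, small_pairs):
        m = train_cnn(small_pairs[:1], _toy_config(iters=3))
        p = tmp_path / "cnn.h5"
        save_cnn(m, p)
        back = load_cnn(p)
        for name in ("W1", "B1", "W2", "B2", "W3", "B3"):
            np.testing.assert_array_equal(getattr(back, name), getattr(m, name))
        assert back.config == m.config
        np.testing.assert_array_equal(back.loss_history, m.loss_history)
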