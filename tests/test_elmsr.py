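"""Random-feature (ELM) engine: features, closed-form ridge fit, inference."""

import numpy as np
import pytest

from lenssr.elmsr import (
    ElmConfig,
    ElmModel,
    _hidden,
    apply_elmsr,
    extract_features,
    load_elm,
    save_elm,
    train_elm,
)
from lenssr.resample import ResampleConfig, hf_decompose, upsample_bicubic


class TestFeatureExtraction:
    def test_48px_image_yields_2116_patch_columns(self, rng):
        feats = extract_features(rng.random((48, 48)))
        assert feats.X.shape == (14, 46 * 46)
        assert feats.X.shape[1] == 2116

    def test_constant_image_has_zero_derivative_rows(self):
        feats = extract_features(np.full((10, 10), 0.7))
        assert np.abs(feats.X[9:]).max() == 0.0
        np.testing.assert_allclose(feats.X[:9], 0.7)

    def test_horizontal_ramp_derivatives(self):
        """Hand-evaluated finite-difference stencils on I(r, c) = c / W."""
        w = 16
        img = np.tile(np.arange(w) / w, (12, 1))
        feats = extract_features(img)
        np.testing.assert_allclose(feats.X[9], 1.0 / w, atol=1e-14)  # d/dx
        for row in (10, 11, 12, 13):
            np.testing.assert_allclose(feats.X[row], 0.0, atol=1e-14)

    def test_column_order_is_raster_scan_of_centers(self, rng):
        img = rng.random((5, 6))
        feats = extract_features(img)
        assert feats.centers[0].tolist() == [1, 1]
        assert feats.centers[-1].tolist() == [3, 4]
        # center intensity of column k is the pixel at its recorded center
        np.testing.assert_allclose(
            feats.X[4], img[feats.centers[:, 0], feats.centers[:, 1]]
        )

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            extract_features(np.ones((2, 5)))


class TestTraining:
    def test_zero_hf_library_gives_zero_beta(self, rcfg):
        pairs = [hf_decompose(np.full((24, 24), v), rcfg) for v in (0.2, 0.5)]
        model = train_elm(pairs, ElmConfig(seed=0))
        np.testing.assert_array_equal(model.beta, 0.0)

    def test_beta_matches_generic_ridge_solver(self, rng):
        """Closed-form ridge vs an independent lstsq on the augmented system."""
        L, n, C = 8, 50, 512.0
        H = 1.0 / (1.0 + np.exp(-rng.normal(size=(L, n))))
        T = rng.normal(size=n)
        gram = H @ H.T + np.eye(L) / C
        beta = np.linalg.solve(gram, H @ T)
        # oracle: ridge as an augmented least-squares problem
        A_aug = np.vstack([H.T, np.eye(L) / np.sqrt(C)])
        b_aug = np.concatenate([T, np.zeros(L)])
        beta_oracle = np.linalg.lstsq(A_aug, b_aug, rcond=None)[0]
        assert np.abs(beta - beta_oracle).max() < 1e-9

    def test_training_beta_matches_formula_on_small_pairs(self, rcfg, small_pairs):
        cfg = ElmConfig(seed=3)
        model = train_elm(small_pairs[:2], cfg)
        X = np.concatenate(
            [extract_features(p.lr_int).X for p in small_pairs[:2]], axis=1
        )
        T = np.concatenate([p.hf[1:-1, 1:-1].ravel() for p in small_pairs[:2]])
        H = _hidden(model.A, model.B, X)
        beta_oracle = np.linalg.lstsq(
            np.vstack([H.T, np.eye(cfg.L) / np.sqrt(cfg.C)]),
            np.concatenate([T, np.zeros(cfg.L)]),
            rcond=None,
        )[0]
        scale = np.abs(beta_oracle).max()
        assert np.abs(model.beta - beta_oracle).max() / scale < 1e-9

    def test_feature_matrix_scales_with_library_size(self, small_pairs):
        X = np.concatenate([extract_features(p.lr_int).X for p in small_pairs], axis=1)
        assert X.shape == (14, len(small_pairs) * 2116)

    def test_interpolation_regime_drives_mse_down(self, rng, rcfg):
        """With L >= columns and huge C, random features fit a tiny set exactly."""
        X = rng.random((14, 10))
        T = rng.normal(size=10)
        cfg = ElmConfig(L=64, C=1e12, seed=0)
        gen = np.random.default_rng(cfg.seed)
        A = gen.uniform(-1, 1, (cfg.L, 14))
        B = gen.uniform(0, 1, cfg.L)
        H = _hidden(A, B, X)
        gram = H @ H.T + np.eye(cfg.L) / cfg.C
        beta = np.linalg.solve(gram, H @ T)
        assert np.mean((beta @ H - T) ** 2) < 1e-6

    def test_same_seed_reproduces_model_bitwise(self, small_pairs):
        m1 = train_elm(small_pairs[:3], ElmConfig(seed=9))
        m2 = train_elm(small_pairs[:3], ElmConfig(seed=9))
        for attr in ("A", "B", "beta"):
            np.testing.assert_array_equal(getattr(m1, attr), getattr(m2, attr))

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            train_elm([], ElmConfig())


class TestInference:
    def test_zero_beta_reduces_to_bicubic(self, rng, rcfg):
        cfg = ElmConfig(seed=0)
        gen = np.random.default_rng(0)
        model = ElmModel(
            A=gen.uniform(-1, 1, (cfg.L, 14)),
            B=gen.uniform(0, 1, cfg.L),
            beta=np.zeros(cfg.L),
            config=cfg,
        )
        lr = rng.random((12, 12))
        out = apply_elmsr(lr, model)
        np.testing.assert_array_equal(out, np.clip(upsample_bicubic(lr, rcfg), 0, 1))

    def test_output_size_is_t_times_input(self, rng, small_pairs):
        model = train_elm(small_pairs[:2], ElmConfig(seed=1))
        assert apply_elmsr(rng.random((12, 12)), model).shape == (48, 48)

    def test_interior_pixel_matches_scalar_loop(self, rng, small_pairs):
        """Unvectorized per-pixel evaluation of beta . sigmoid(A x + B)."""
        model = train_elm(small_pairs[:2], ElmConfig(seed=1))
        lr = np.clip(small_pairs[2].lr, 0, 1)
        lr_int = upsample_bicubic(lr, ResampleConfig(t=model.config.t))
        out = apply_elmsr(lr, model)
        for r, c in [(10, 10), (24, 30), (1, 1)]:
            patch = lr_int[r - 1 : r + 2, c - 1 : c + 2]
            x = np.empty(14)
            x[:9] = patch.ravel()
            x[9] = (patch[1, 2] - patch[1, 0]) / 2
            x[10] = (patch[2, 1] - patch[0, 1]) / 2
            x[11] = patch[1, 2] - 2 * patch[1, 1] + patch[1, 0]
            x[12] = patch[2, 1] - 2 * patch[1, 1] + patch[0, 1]
            x[13] = (patch[2, 2] - patch[2, 0] - patch[0, 2] + patch[0, 0]) / 4
            hf = sum(
                model.beta[i] / (1.0 + np.exp(-(model.A[i] @ x + model.B[i])))
                for i in range(model.config.L)
            )
            expected = np.clip(lr_int[r, c] + hf, 0, 1)
            assert abs(out[r, c] - expected) < 1e-12


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path, small_pairs):
        model = train_elm(small_pairs[:2], ElmConfig(seed=5))
        p = tmp_path / "elm.h5"
        save_elm(model, p)
        back = load_elm(p)
        np.testing.assert_array_equal(back.beta, model.beta)
        np.testing.assert_array_equal(back.A, model.A)
        assert back.config == model.config
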