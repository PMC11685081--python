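"""SE block against explicit loop/matrix oracles, regressor contracts,
augmentation semantics, and the linear-readout recovery bound."""

import numpy as np
import pytest

from nutriseg import nn
from nutriseg.dataset_io import apply_mask
from nutriseg.metrics import evaluate
from nutriseg.regression import (
    RegNetConfig, SEConfig, SEModule, augment, build_regressor,
    color_area_features, excite, predict_nutrients, recalibrate, squeeze,
)
from nutriseg.synthetic import DEFAULT_PALETTE, SceneConfig, generate_dishes


class TestSqueezeExciteRecalibrate:
    def test_constant_channels_squeeze_to_their_value(self):
        x = np.stack([np.full((4, 6), v) for v in (1.0, -2.0, 7.5)])
        np.testing.assert_allclose(squeeze(x), [1.0, -2.0, 7.5])

    def test_squeeze_hand_mean(self):
        assert squeeze(np.array([[[1.0, 2.0], [3.0, 4.0]]]))[0] == pytest.approx(2.5)

    def test_squeeze_matches_double_loop(self, rng):
        x = rng.normal(size=(8, 5, 7))
        expected = np.zeros(8)
        for c in range(8):
            for i in range(5):
                for j in range(7):
                    expected[c] += x[c, i, j]
        expected /= 5 * 7
        np.testing.assert_allclose(squeeze(x), expected, atol=1e-10)

    def test_excite_zero_weights_give_half(self):
        z = np.ones(8)
        s = excite(z, np.zeros((2, 8)), np.zeros((8, 2)))
        np.testing.assert_allclose(s, 0.5)

    def test_excite_matches_matrix_composition_and_range(self, rng):
        c, r = 8, 2
        z = rng.normal(size=c)
        w1 = rng.normal(size=(c // r, c))
        w2 = rng.normal(size=(c, c // r))
        expected = 1 / (1 + np.exp(-(w2 @ np.maximum(w1 @ z, 0))))
        got = excite(z, w1, w2)
        np.testing.assert_allclose(got, expected, atol=1e-10)
        assert ((got > 0) & (got < 1)).all()

    def test_recalibrate_identity_zero_and_channel_sums(self, rng):
        x = rng.normal(size=(6, 4, 4))
        np.testing.assert_allclose(recalibrate(x, np.ones(6)), x)
        assert recalibrate(x, np.zeros(6)).sum() == 0
        s = rng.uniform(0.1, 0.9, size=6)
        np.testing.assert_allclose(recalibrate(x, s).sum(axis=(1, 2)),
                                   s * x.sum(axis=(1, 2)), atol=1e-10)

    def test_shape_errors(self, rng):
        with pytest.raises(ValueError):
            excite(np.ones(8), np.zeros((2, 7)), np.zeros((8, 2)))
        with pytest.raises(ValueError):
            recalibrate(rng.normal(size=(6, 4, 4)), np.ones(5))

    def test_bottleneck_rounds_up(self):
        assert SEConfig(channels=10, reduction=4).bottleneck == 3

    def test_se_module_preserves_shape_and_is_contractive(self, rng):
        se = SEModule(SEConfig(channels=8, reduction=2), rng)
        x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
        out = se(nn.Tensor(x)).numpy()
        assert out.shape == x.shape
        # s in (0,1) channel weights: output never exceeds input magnitude
        assert (np.abs(out) <= np.abs(x) + 1e-6).all()


class TestRegressor:
    def test_forward_emits_five_finite_outputs(self, rng):
        model = build_regressor(RegNetConfig(backbone="small", head_dims=(32, 16)), seed=0)
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        out = model(nn.Tensor(x)).numpy()
        assert out.shape == (1, 5)
        assert np.isfinite(out).all()

    def test_se_bypass_changes_outputs(self, rng):
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        on = build_regressor(RegNetConfig(backbone="tiny", se_enabled=True, head_dims=(16,)), seed=1)
        off = build_regressor(RegNetConfig(backbone="tiny", se_enabled=False, head_dims=(16,)), seed=1)
        assert not np.allclose(on(nn.Tensor(x)).numpy(), off(nn.Tensor(x)).numpy())

    def test_unknown_backbone_lists_options(self):
        with pytest.raises(ValueError, match="small"):
            build_regressor(RegNetConfig(backbone="resnet999"))

    def test_predictions_clamped_nonnegative(self, rng):
        model = build_regressor(RegNetConfig(backbone="tiny", head_dims=(8,)), seed=2)
        model.heads[-1].bias.data[:] = -100.0
        imgs = [rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)]
        assert (predict_nutrients(model, imgs) >= 0).all()


class TestAugment:
    def test_forced_flip_is_involution(self, rng):
        img = rng.integers(0, 255, (16, 20, 3)).astype(np.uint8)
        once = augment(img, rng, force_flip=True)
        twice = augment(once, rng, force_flip=True)
        assert np.array_equal(twice, img)

    def test_crop_to_own_size_is_identity(self, rng):
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        out = augment(img, rng, crop_size=16, force_flip=False)
        assert np.array_equal(out, img)

    def test_oversized_crop_rejected(self, rng):
        img = np.zeros((16, 16, 3), np.uint8)
        with pytest.raises(ValueError, match="larger than image"):
            augment(img, rng, crop_size=17)

    def test_fixed_seed_reproduces_batch(self, rng):
        imgs = [rng.integers(0, 255, (24, 24, 3)).astype(np.uint8) for _ in range(6)]
        a = [augment(im, np.random.default_rng(5), crop_size=16) for im in imgs]
        b = [augment(im, np.random.default_rng(5), crop_size=16) for im in imgs]
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestLinearReadout:
    def test_color_area_least_squares_recovers_labels(self):
        """On noiseless scenes, per-ingredient color areas plus a linear map
        reach < 1% PMAE — the floor for any learned regressor."""
        dishes = [d.record for d in
                  generate_dishes(SceneConfig(image_size=(64, 64), seed=5), 200)]
        X = np.stack([color_area_features(apply_mask(r.image, r.mask), DEFAULT_PALETTE)
                      for r in dishes])
        Y = np.stack([r.label.as_array() for r in dishes])
        Xtr = np.hstack([X[:160], np.ones((160, 1))])
        Xte = np.hstack([X[160:], np.ones((len(X) - 160, 1))])
        W, *_ = np.linalg.lstsq(Xtr, Y[:160], rcond=None)
        report = evaluate(np.maximum(Xte @ W, 0), Y[160:])
        assert report.mean_pmae < 1.0
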