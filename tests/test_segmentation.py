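"""UNet contracts, training schedule, and the four overlap metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutriseg import nn
from nutriseg.dataset_io import DishRecord, NutrientLabel
from nutriseg.segmentation import (
    ConfusionCounts, SegNetConfig, SegTrainConfig, build_unet, confusion, dice,
    jaccard, precision, predict_mask, recall, train_segmenter,
)


def _zero_label():
    return NutrientLabel(0, 0, 0, 0, 0)


class TestUNet:
    def test_output_shape_matches_input(self):
        net = build_unet(SegNetConfig(n_stages=4, base_channels=4), seed=0)
        out = net(nn.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        assert out.shape == (1, 1, 64, 64)

    def test_indivisible_input_raises_shape_error(self):
        net = build_unet(SegNetConfig(n_stages=4, base_channels=4), seed=0)
        with pytest.raises(ValueError, match="not divisible by 2\\^4"):
            net(nn.Tensor(np.zeros((1, 3, 60, 60), dtype=np.float32)))

    def test_parameter_count_matches_layerwise_formula(self):
        # 2 stages, base 4: channels 3->4->8, bottleneck 16, decoders mirror.
        net = build_unet(SegNetConfig(n_stages=2, base_channels=4), seed=0)

        def conv(ci, co, k):
            return co * ci * k * k + co

        expected = (
            conv(3, 4, 3) + conv(4, 4, 3)          # encoder stage 0
            + conv(4, 8, 3) + conv(8, 8, 3)        # encoder stage 1
            + conv(8, 16, 3) + conv(16, 16, 3)     # bottleneck
            + (16 * 8 * 4 + 8) + (8 * 4 * 4 + 4)   # transposed convs (k=2)
            + conv(16, 8, 3) + conv(8, 8, 3)       # decoder stage 1 (after skip concat)
            + conv(8, 4, 3) + conv(4, 4, 3)        # decoder stage 0
            + conv(4, 1, 1)                        # 1x1 head
        )
        assert sum(p.data.size for p in net.parameters()) == expected

    def test_forward_deterministic_for_fixed_seed(self, rng):
        x = rng.random((1, 3, 16, 16)).astype(np.float32)
        a = build_unet(SegNetConfig(n_stages=2, base_channels=4), seed=3)
        b = build_unet(SegNetConfig(n_stages=2, base_channels=4), seed=3)
        assert np.array_equal(a(nn.Tensor(x)).numpy(), b(nn.Tensor(x)).numpy())


class TestTraining:
    def test_lr_schedule_values(self):
        # decay 0.99 per epoch from the configured starting rate
        from nutriseg.nn import Adam, ExponentialDecay, Tensor
        sched = ExponentialDecay(Adam([Tensor(np.zeros(1), requires_grad=True)], lr=0.001))
        assert sched.lr_at(0) == pytest.approx(0.001)
        assert sched.lr_at(2) == pytest.approx(0.0009801)

    def test_loss_decreases_on_small_problem(self, small_dishes):
        records = [d.record for d in small_dishes]
        net = build_unet(SegNetConfig(n_stages=2, base_channels=4), seed=42)
        trace = train_segmenter(net, records,
                                SegTrainConfig(epochs=4, lr0=2e-3, seed=42, batch_size=4))
        assert trace[-1] < trace[0]

    def test_missing_mask_rejected_before_training(self, rng):
        rec = DishRecord("d", rng.integers(0, 255, (16, 16, 3)).astype(np.uint8),
                         _zero_label(), mask=None)
        net = build_unet(SegNetConfig(n_stages=2, base_channels=4), seed=0)
        with pytest.raises(ValueError, match="no mask"):
            train_segmenter(net, [rec], SegTrainConfig(epochs=1))


class TestPredictMask:
    def test_threshold_boundaries(self, rng):
        net = build_unet(SegNetConfig(n_stages=2, base_channels=4), seed=0)
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        # push the head bias to +-20: sigmoid saturates to ~1 / ~0
        net.head.bias.data[:] = 20.0
        assert predict_mask(net, img).all()
        net.head.bias.data[:] = -20.0
        assert not predict_mask(net, img).any()
        net.head.bias.data[:] = 0.0
        assert not predict_mask(net, img, threshold=1.0).any()


class TestConfusionAndMetrics:
    def test_perfect_prediction_counts(self):
        truth = np.zeros((20, 20), np.uint8)
        truth[:10, :10] = 1  # 100 food px of 400
        c = confusion(truth, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (100, 0, 0, 300)
        for metric in (dice, jaccard, precision, recall):
            assert metric(c) == 1.0

    def test_all_zero_prediction(self):
        truth = np.zeros((20, 20), np.uint8)
        truth[:10, :10] = 1
        c = confusion(np.zeros_like(truth), truth)
        assert (c.tp, c.fn) == (0, 100)
        assert recall(c) == 0.0

    def test_counts_match_pixel_loop(self, rng):
        pred = (rng.random((32, 32)) < 0.4).astype(np.uint8)
        truth = (rng.random((32, 32)) < 0.3).astype(np.uint8)
        c = confusion(pred, truth)
        tp = fp = fn = tn = 0
        for i in range(32):
            for j in range(32):
                if pred[i, j] and truth[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 32 * 32

    def test_half_coverage_hand_values(self):
        c = ConfusionCounts(tp=50, fp=0, fn=50, tn=100)
        assert dice(c) == pytest.approx(2 / 3)
        assert jaccard(c) == pytest.approx(0.5)
        assert precision(c) == 1.0
        assert recall(c) == 0.5

    @given(tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000))
    @settings(max_examples=1000, deadline=None)
    def test_jaccard_dice_identity(self, tp, fp, fn):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=10)
        d, j = dice(c), jaccard(c)
        assert j == pytest.approx(d / (2 - d), abs=1e-12)
        assert d >= j
        if d not in (0.0, 1.0):
            assert d > j

    def test_metrics_invariant_under_joint_transforms(self, rng):
        pred = (rng.random((16, 24)) < 0.4).astype(np.uint8)
        truth = (rng.random((16, 24)) < 0.3).astype(np.uint8)
        base = [m(confusion(pred, truth)) for m in (dice, jaccard, precision, recall)]
        for tf in (np.transpose, np.flipud, np.fliplr):
            got = [m(confusion(tf(pred), tf(truth))) for m in (dice, jaccard, precision, recall)]
            assert got == base

    def test_both_empty_masks_score_one(self):
        c = confusion(np.zeros((4, 4)), np.zeros((4, 4)))
        assert dice(c) == jaccard(c) == precision(c) == recall(c) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            confusion(np.zeros((4, 4)), np.zeros((5, 5)))
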