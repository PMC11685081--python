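"""Loss and metric arithmetic: hand examples, printed-table aggregation
twins, and the loss = PMAE/100 identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutriseg import nn
from nutriseg.dataset_io import NUTRIENTS
from nutriseg.metrics import (
    evaluate, mae, mse, multitask_loss_tensor, pmae, r2, rmse, subtask_loss,
    total_loss,
)

# Published per-nutrient PMAE rows (calorie, mass, fat, carb, protein) and
# the mean each row aggregates to.
BACKBONE_PMAE_ROWS = {
    "GoogLeNet": ((27.87, 24.27, 44.65, 47.53, 40.28), 36.92),
    "GoogLeNetV3": ((20.59, 16.41, 32.0, 28.25, 28.15), 25.08),
    "DenseNet121": ((19.67, 14.53, 30.33, 24.77, 26.4), 23.14),
    "ViTb32": ((17.78, 14.83, 27.8, 23.9, 24.2), 21.70),
    "MobileNetv3": ((18.98, 13.91, 28.85, 23.13, 23.24), 21.62),
    "ShuffleNetV2": ((18.11, 13.94, 28.29, 23.0, 23.54), 21.37),
    "ViTb16": ((16.83, 13.32, 24.87, 21.2, 21.37), 19.52),
    "VGG": ((16.21, 12.02, 24.66, 19.29, 20.44), 18.52),
    "Resnet50": ((16.48, 11.87, 24.18, 19.9, 19.24), 18.33),
    "Ours": ((15.68, 11.75, 21.41, 18.79, 17.68), 17.06),
}


class TestSubtaskLoss:
    def test_perfect_is_zero(self):
        assert subtask_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert subtask_loss([11, 18, 33], [10, 20, 30]) == pytest.approx(0.1)

    def test_scale_invariance(self, rng):
        y = rng.uniform(1, 100, size=20)
        y_hat = y + rng.normal(0, 5, size=20)
        base = subtask_loss(y_hat, y)
        for c in (0.01, 3.0, 1e4):
            assert subtask_loss(c * y_hat, c * y) == pytest.approx(base, rel=1e-12)

    def test_all_zero_truth_conventions(self):
        with pytest.warns(UserWarning, match="all true values are zero"):
            assert subtask_loss([1.0, 2.0], [0.0, 0.0]) == pytest.approx(3.0)
        assert subtask_loss([0.0], [0.0]) == 0.0


class TestTotalLoss:
    def test_sums_the_five_subtasks(self, rng):
        y = rng.uniform(1, 100, size=(12, 5))
        y_hat = y + rng.normal(0, 2, size=(12, 5))
        expected = sum(subtask_loss(y_hat[:, m], y[:, m]) for m in range(5))
        assert total_loss(y_hat, y) == pytest.approx(expected, rel=1e-12)

    def test_each_subtask_at_tenth_gives_half(self):
        y = np.full((3, 5), 10.0)
        y_hat = y * 1.1  # every subtask loss = 0.1
        assert total_loss(y_hat, y) == pytest.approx(0.5)

    def test_invariant_to_per_subtask_unit_rescaling(self, rng):
        # the stated purpose: magnitude differences between nutrients cancel
        y = rng.uniform(1, 100, size=(10, 5))
        y_hat = y + rng.normal(0, 3, size=(10, 5))
        scale = np.array([1000.0, 0.01, 7.0, 1.0, 42.0])
        assert total_loss(y_hat * scale, y * scale) == pytest.approx(
            total_loss(y_hat, y), rel=1e-12)

    def test_tensor_loss_agrees_with_numpy(self, rng):
        y = rng.uniform(1, 100, size=(8, 5)).astype(np.float32)
        y_hat = (y + rng.normal(0, 2, size=(8, 5))).astype(np.float32)
        t = multitask_loss_tensor(nn.Tensor(y_hat), y)
        assert t.item() == pytest.approx(total_loss(y_hat, y), rel=1e-4)


class TestScalarMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mae(y, y) == mse(y, y) == rmse(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_hand_arithmetic(self):
        y, y_hat = np.array([0.0, 2.0]), np.array([1.0, 1.0])
        assert mae(y_hat, y) == 1.0
        assert mse(y_hat, y) == 1.0
        assert rmse(y_hat, y) == 1.0
        assert r2(y_hat, y) == 0.0

    def test_rmse_squares_to_mse(self, rng):
        y = rng.normal(size=30)
        y_hat = rng.normal(size=30)
        assert rmse(y_hat, y) ** 2 == pytest.approx(mse(y_hat, y), rel=1e-12)

    def test_r2_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(r2([1.0, 2.0], [3.0, 3.0]))

    def test_pmae_hand_value_and_zero_mean_error(self):
        assert pmae([11, 18, 33], [10, 20, 30]) == pytest.approx(10.0)
        with pytest.raises(ValueError, match="positive mean"):
            pmae([1.0], [0.0])


class TestLossPmaeIdentity:
    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=200, deadline=None)
    def test_subtask_loss_equals_pmae_over_100(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        y = rng.uniform(0.1, 500, size=n)
        y_hat = np.abs(y + rng.normal(0, 20, size=n))
        assert abs(subtask_loss(y_hat, y) - pmae(y_hat, y) / 100.0) <= \
            1e-12 * max(1.0, pmae(y_hat, y) / 100.0)


class TestEvaluate:
    @pytest.mark.parametrize("row,mean", [v for v in BACKBONE_PMAE_ROWS.values()],
                             ids=list(BACKBONE_PMAE_ROWS))
    def test_mean_pmae_aggregation_reproduces_published_rows(self, row, mean):
        # build a batch whose per-nutrient PMAEs equal the printed row
        # (truths mean 100, predictions offset by the row value), then check
        # the report's mean PMAE against the printed mean
        y = np.tile([50.0, 150.0], (5, 1)).T  # 2 samples x 5 nutrients
        y_hat = y + np.asarray(row)
        report = evaluate(y_hat, y)
        per = [report.per_nutrient[n]["pmae"] for n in NUTRIENTS]
        np.testing.assert_allclose(per, row, rtol=1e-12)
        # printed means are rounded from unrounded components, so the mean of
        # the printed components can differ in the last digit (ShuffleNetV2)
        assert abs(report.mean_pmae - mean) <= 0.011

    def test_mean_pmae_is_unweighted_mean_of_components(self, rng):
        y = rng.uniform(1, 100, size=(20, 5))
        y_hat = np.abs(y + rng.normal(0, 5, size=(20, 5)))
        report = evaluate(y_hat, y)
        per = [report.per_nutrient[n]["pmae"] for n in NUTRIENTS]
        assert report.mean_pmae == pytest.approx(np.mean(per), rel=1e-12)

    def test_permutation_invariance_over_samples(self, rng):
        y = rng.uniform(1, 100, size=(15, 5))
        y_hat = np.abs(y + rng.normal(0, 5, size=(15, 5)))
        perm = rng.permutation(15)
        assert evaluate(y_hat[perm], y[perm]).mean_pmae == pytest.approx(
            evaluate(y_hat, y).mean_pmae, rel=1e-12)

    def test_zero_error_batch_report(self):
        y = np.abs(np.random.default_rng(1).normal(2, 1, size=(10, 5))) + 0.5
        report = evaluate(y.copy(), y)
        for n in NUTRIENTS:
            row = report.per_nutrient[n]
            assert row["pmae"] == row["mae"] == row["mse"] == row["rmse"] == 0.0
            assert row["r2"] == 1.0
        assert report.mean_pmae == 0.0

    def test_scatter_pairs_and_csv_export(self, tmp_path, rng):
        y = rng.uniform(1, 100, size=(6, 5))
        y_hat = np.abs(y + rng.normal(0, 5, size=(6, 5)))
        report = evaluate(y_hat, y)
        np.testing.assert_allclose(report.scatter["mass"][:, 0], y[:, 0])
        np.testing.assert_allclose(report.scatter["mass"][:, 1], y_hat[:, 0])
        report.export_scatter(tmp_path)
        report.to_csv(tmp_path / "report.csv")
        assert (tmp_path / "scatter_protein.csv").exists()
        assert "mean_pmae" in (tmp_path / "report.csv").read_text()
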