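"""Confusion counts, derived metrics, and connected-component cleanup."""

import numpy as np
import pytest

from angioseg.metrics import (ConfusionCounts, confusion, default_min_area,
                              evaluate, evaluate_masks, metrics_from_counts,
                              remove_small_components)
from angioseg.network import NetworkConfig
from angioseg.nn.tensor import Tensor


class TestConfusion:
    def test_perfect_prediction_no_errors(self):
        m = (np.random.default_rng(0).random((10, 10)) > 0.5).astype(np.uint8)
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0
        assert c.total == 100

    def test_all_ones_prediction_counting(self):
        truth = np.zeros((10, 10), np.uint8)
        truth.flat[:10] = 1
        c = confusion(np.ones((10, 10), np.uint8), truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 90, 0, 0)

    def test_all_zeros_prediction_boundary_rates(self):
        truth = np.zeros((10, 10), np.uint8)
        truth.flat[:10] = 1
        m = metrics_from_counts(confusion(np.zeros((10, 10), np.uint8),
                                          truth))
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.full((4, 4), 2), np.zeros((4, 4)))


class TestMetricsFromCounts:
    def test_sensitivity_arithmetic(self):
        m = metrics_from_counts(ConfusionCounts(tp=3, tn=0, fp=1, fn=1))
        assert m.sensitivity == pytest.approx(0.75)

    def test_iou_dice_identity_case(self):
        m = metrics_from_counts(ConfusionCounts(tp=3, tn=9, fp=2, fn=2))
        assert m.iou_vessel == pytest.approx(3 / 7)
        assert m.dice == pytest.approx(0.6)
        assert m.iou_vessel == pytest.approx(m.dice / (2 - m.dice))

    def test_absent_background_convention(self):
        m = metrics_from_counts(ConfusionCounts(tp=16, tn=0, fp=0, fn=0))
        assert m.specificity == 1.0
        assert m.iou_background == 1.0

    def test_absent_vessel_convention(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, tn=16, fp=0, fn=0))
        assert m.sensitivity == 1.0 and m.iou_vessel == 1.0 and m.dice == 1.0

    def test_missed_class_scores_zero(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, tn=12, fp=0, fn=4))
        assert m.sensitivity == 0.0 and m.iou_vessel == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="no pixels"):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_accuracy_bounded_by_class_rates(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            c = ConfusionCounts(*rng.integers(1, 50, size=4))
            m = metrics_from_counts(c)
            lo = min(m.sensitivity, m.specificity) - 1e-12
            hi = max(m.sensitivity, m.specificity) + 1e-12
            assert lo <= m.accuracy <= hi


class TestRemoveSmallComponents:
    def _specked(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[5:30, 5:25] = 1                      # 500 px component
        specks = [(2, 35), (35, 2), (38, 38)]
        for r, c in specks:
            mask[r, c] = 1
        return mask, specks

    def test_specks_removed_major_component_untouched(self):
        mask, specks = self._specked()
        out = remove_small_components(mask, min_area=50)
        assert all(out[r, c] == 0 for r, c in specks)
        np.testing.assert_array_equal(out[5:30, 5:25], 1)
        assert out.sum() == 500

    def test_empty_mask_passthrough(self):
        out = remove_small_components(np.zeros((8, 8), np.uint8), 10)
        assert out.sum() == 0

    def test_zero_min_area_is_identity(self):
        mask, _ = self._specked()
        np.testing.assert_array_equal(remove_small_components(mask, 0), mask)

    def test_negative_min_area_rejected(self):
        with pytest.raises(ValueError, match="min_area"):
            remove_small_components(np.zeros((4, 4), np.uint8), -1)

    def test_never_adds_pixels(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mask = (rng.random((32, 32)) > 0.7).astype(np.uint8)
            out = remove_small_components(mask, 5)
            assert (out <= mask).all()

    def test_cleanup_raises_vessel_iou_when_specks_are_false_positives(self):
        truth = np.zeros((40, 40), np.uint8)
        truth[5:30, 5:25] = 1
        pred, _ = self._specked()              # truth plus specks
        before = metrics_from_counts(confusion(pred, truth)).iou_vessel
        cleaned = remove_small_components(pred, 50)
        after = metrics_from_counts(confusion(cleaned, truth)).iou_vessel
        assert after > before
        assert after == 1.0

    def test_default_min_area_scales_with_resolution(self):
        assert default_min_area(448) == 64
        assert default_min_area(96) == 3


class _OracleModel:
    """Stub network that returns preset probability maps."""

    def __init__(self, probs, n=1, size=64):
        self._probs = np.asarray(probs, np.float32)
        self.config = NetworkConfig(n=n, input_size=size,
                                    width_multiplier=0.25)
        self._cursor = 0

    def __call__(self, batch):
        b = batch.shape[0]
        out = self._probs[self._cursor:self._cursor + b]
        self._cursor += b
        return Tensor(out[:, None])


class TestEvaluate:
    def test_oracle_predictions_score_one_everywhere(self):
        rng = np.random.default_rng(1)
        y = (rng.random((6, 64, 64)) > 0.6).astype(np.uint8)
        model = _OracleModel(y.astype(np.float32))
        x = rng.random((6, 3, 64, 64)).astype(np.float32)
        report = evaluate(model, x, y)
        for v in report.per_image_mean.as_dict().values():
            assert v == pytest.approx(1.0)
        assert report.pooled.iou_vessel == pytest.approx(1.0)

    def test_all_background_prediction_has_zero_sensitivity(self):
        rng = np.random.default_rng(2)
        y = (rng.random((4, 64, 64)) > 0.6).astype(np.uint8)
        model = _OracleModel(np.zeros((4, 64, 64), np.float32))
        x = rng.random((4, 3, 64, 64)).astype(np.float32)
        report = evaluate(model, x, y)
        assert report.per_image_mean.sensitivity == 0.0
        assert report.pooled.sensitivity == 0.0

    def test_post_processing_improves_specked_predictions(self):
        rng = np.random.default_rng(3)
        truth = np.zeros((2, 64, 64), np.uint8)
        truth[:, 10:40, 10:40] = 1
        probs = truth.astype(np.float32).copy()
        for i in range(2):                      # speck false positives
            for _ in range(6):
                r, c = rng.integers(0, 64, 2)
                if truth[i, r, c] == 0:
                    probs[i, r, c] = 1.0
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        raw = evaluate(_OracleModel(probs), x, truth, post_process=False)
        clean = evaluate(_OracleModel(probs), x, truth, post_process=True,
                         min_area=10)
        assert clean.per_image_mean.iou_vessel > raw.per_image_mean.iou_vessel

    def test_empty_test_set_rejected(self):
        model = _OracleModel(np.zeros((0, 64, 64)))
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, np.zeros((0, 3, 64, 64)), np.zeros((0, 64, 64)))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="predictions"):
            evaluate_masks([np.zeros((4, 4), np.uint8)], [])
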