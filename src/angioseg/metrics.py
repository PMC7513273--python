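"""Pixel-level evaluation and connected-component post-processing.

Vessel is the positive class.  Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), accuracy = (TP+TN)/total, IOU(vessel) = TP/(TP+FP+FN),
IOU(background) = TN/(TN+FP+FN), dice = 2TP/(2TP+FP+FN); a ratio with a zero
denominator is reported as 1 when the class is absent from both masks and 0
otherwise.  Reports carry both aggregation modes: the mean of per-image
metrics and metrics of the pixel-pooled confusion counts.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence

import numpy as np
from skimage import measure

from .network import STNet, predict_proba

DEFAULT_MIN_AREA_AT_448 = 64
PREDICTION_THRESHOLD = 0.5


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclasses.dataclass
class MetricsValues:
    sensitivity: float
    specificity: float
    accuracy: float
    iou_vessel: float
    iou_background: float
    dice: float

    def as_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class MetricsReport:
    per_image_mean: MetricsValues
    pooled: MetricsValues
    counts: ConfusionCounts            # pooled counts
    n_images: int
    aggregation: str = "per_image_mean"

    @property
    def primary(self) -> MetricsValues:
        return (self.per_image_mean if self.aggregation == "per_image_mean"
                else self.pooled)


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} mask is not binary")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies; vessel (1) is the positive class."""
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, absent_in_both: bool) -> float:
    if den == 0:
        return 1.0 if absent_in_both else 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricsValues:
    """All evaluation metrics from one confusion table."""
    if c.total == 0:
        raise ValueError("no pixels to evaluate")
    no_vessel_truth = c.tp + c.fn == 0
    no_vessel_pred = c.tp + c.fp == 0
    no_bg_truth = c.tn + c.fp == 0
    no_bg_pred = c.tn + c.fn == 0
    return MetricsValues(
        sensitivity=_ratio(c.tp, c.tp + c.fn,
                           no_vessel_truth and no_vessel_pred),
        specificity=_ratio(c.tn, c.tn + c.fp, no_bg_truth and no_bg_pred),
        accuracy=(c.tp + c.tn) / c.total,
        iou_vessel=_ratio(c.tp, c.tp + c.fp + c.fn,
                          no_vessel_truth and no_vessel_pred),
        iou_background=_ratio(c.tn, c.tn + c.fp + c.fn,
                              no_bg_truth and no_bg_pred),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn,
                    no_vessel_truth and no_vessel_pred),
    )


def default_min_area(size: int) -> int:
    """Speck-removal threshold, scaled from 64 px at 448x448 by area."""
    return max(1, int(round(DEFAULT_MIN_AREA_AT_448 * (size / 448.0) ** 2)))


def remove_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Delete 8-connected components smaller than ``min_area`` pixels.

    Surviving components are bit-identical to the input; ``min_area`` 0 is
    the identity.
    """
    if min_area < 0:
        raise ValueError(f"min_area must be >= 0, got {min_area}")
    arr = _check_binary(mask, "input")
    if min_area == 0 or not arr.any():
        return arr.astype(np.uint8)
    labels = measure.label(arr, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels].astype(np.uint8)


def _aggregate(per_image: Sequence[MetricsValues]) -> MetricsValues:
    fields = [f.name for f in dataclasses.fields(MetricsValues)]
    return MetricsValues(**{f: float(np.mean([getattr(m, f) for m in per_image]))
                            for f in fields})


def evaluate_masks(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray],
                   aggregation: str = "per_image_mean") -> MetricsReport:
    """Score predicted binary masks against ground truth."""
    if len(preds) == 0:
        raise ValueError("empty evaluation set")
    if len(preds) != len(truths):
        raise ValueError(f"{len(preds)} predictions vs {len(truths)} truths")
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for p, t in zip(preds, truths):
        c = confusion(p, t)
        per_image.append(metrics_from_counts(c))
        pooled = pooled + c
    return MetricsReport(per_image_mean=_aggregate(per_image),
                         pooled=metrics_from_counts(pooled),
                         counts=pooled, n_images=len(per_image),
                         aggregation=aggregation)


def evaluate(model: STNet, x: np.ndarray, y: np.ndarray,
             post_process: bool = False,
             min_area: Optional[int] = None,
             aggregation: str = "per_image_mean") -> MetricsReport:
    """Predict test windows, threshold at 0.5, optionally clean, and score."""
    x = np.asarray(x, dtype=np.float32)
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    if x.shape[1] != model.config.depth:
        raise ValueError(
            f"window depth {x.shape[1]} != network depth {model.config.depth}")
    probs = predict_proba(model, x)
    preds = (probs > PREDICTION_THRESHOLD).astype(np.uint8)
    if post_process:
        area = default_min_area(x.shape[-1]) if min_area is None else min_area
        preds = np.stack([remove_small_components(p, area) for p in preds])
    truths = np.asarray(y).astype(np.uint8)
    return evaluate_masks(list(preds), list(truths), aggregation)
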