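"""Scikit-learn style front end for the 3D-2D vessel segmenter.

``VesselSegmenter`` wraps preprocessing, window extraction, network
construction, dice-loss SGD training and thresholded prediction behind the
familiar ``fit`` / ``predict`` / ``score`` surface, so the model composes
with sklearn model selection.  ``X`` is a list of clips, each an ``(L, H, W)``
array of grayscale frames (or a single such array); ``y`` holds the aligned
binary masks.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from . import data as D
from .metrics import (default_min_area, evaluate_masks,
                      remove_small_components, PREDICTION_THRESHOLD)
from .network import NetworkConfig, STNet, predict_proba
from .train import TrainingConfig, train

ClipArray = np.ndarray


def _as_clips(x) -> List[np.ndarray]:
    if isinstance(x, np.ndarray) and x.ndim == 3:
        return [x]
    return [np.asarray(c) for c in x]


class VesselSegmenter(BaseEstimator):
    """Spatio-temporal coronary vessel segmenter.

    Parameters mirror the underlying network and training configuration:
    ``n_context`` is the temporal radius N (window depth 2N+1; 0 yields the
    2D single-frame baseline), ``input_size`` the square network resolution
    (divisible by 32), ``width_multiplier`` scales model capacity.  Training
    uses dice loss + L2 with plain SGD.  ``post_process`` removes connected
    components smaller than ``min_area`` pixels from predicted masks
    (``None``: 64 px at 448x448, scaled by area).

    Attributes (after ``fit``): ``model_`` (the trained network),
    ``loss_log_`` (per-epoch losses), ``config_``, ``train_config_``.
    """

    def __init__(self, n_context: int = 2, input_size: int = 448,
                 width_multiplier: float = 1.0,
                 learning_rate: float = 2e-4, momentum: float = 0.0,
                 batch_size: int = 4, epochs: int = 100, rho: float = 1e-4,
                 dice_smooth: float = 1.0, post_process: bool = True,
                 min_area: Optional[int] = None,
                 pretrained_weights: Optional[str] = None,
                 random_state: int = 0):
        self.n_context = n_context
        self.input_size = input_size
        self.width_multiplier = width_multiplier
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.rho = rho
        self.dice_smooth = dice_smooth
        self.post_process = post_process
        self.min_area = min_area
        self.pretrained_weights = pretrained_weights
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _clip_windows(self, clip: np.ndarray,
                      masks: Optional[np.ndarray]) -> List[D.FrameWindow]:
        frames = [D.preprocess(f, self.input_size) for f in clip]
        if masks is None:
            labels = [np.zeros((self.input_size,) * 2, np.uint8)
                      for _ in frames]
        else:
            labels = [D.preprocess_label(m, self.input_size) for m in masks]
        return D.extract_windows(D.pad_subset(frames, self.n_context),
                                 labels, self.n_context)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: Union[ClipArray, Sequence[ClipArray]],
            y: Union[ClipArray, Sequence[ClipArray]]) -> "VesselSegmenter":
        clips, masks = _as_clips(X), _as_clips(y)
        if len(clips) != len(masks):
            raise ValueError(f"{len(clips)} clips but {len(masks)} mask clips")
        windows: List[D.FrameWindow] = []
        for c, m in zip(clips, masks):
            if len(c) != len(m):
                raise ValueError("clip and mask lengths differ")
            windows.extend(self._clip_windows(c, m))
        xw, yw = D.windows_to_arrays(windows)
        self.config_ = NetworkConfig(
            n=self.n_context, input_size=self.input_size,
            width_multiplier=self.width_multiplier,
            pretrained_weights=self.pretrained_weights)
        self.train_config_ = TrainingConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, rho=self.rho, momentum=self.momentum,
            seed=self.random_state, dice_smooth=self.dice_smooth)
        self.model_ = STNet(self.config_, seed=self.random_state)
        self.loss_log_ = train(self.model_, xw, yw, self.train_config_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this VesselSegmenter instance is not fitted")

    def predict_proba(self, X) -> List[np.ndarray]:
        """Per-clip stacks of vessel probability maps (L, S, S)."""
        self._check_fitted()
        out = []
        for clip in _as_clips(X):
            xw, _ = D.windows_to_arrays(self._clip_windows(clip, None))
            out.append(predict_proba(self.model_, xw))
        return out

    def predict(self, X) -> List[np.ndarray]:
        """Per-clip stacks of binary masks (L, S, S), one per frame."""
        probs = self.predict_proba(X)
        area = (default_min_area(self.input_size) if self.min_area is None
                else self.min_area)
        out = []
        for p in probs:
            masks = (p > PREDICTION_THRESHOLD).astype(np.uint8)
            if self.post_process:
                masks = np.stack([remove_small_components(m, area)
                                  for m in masks])
            out.append(masks)
        return out

    def score(self, X, y) -> float:
        """Mean per-frame vessel IOU over all clips."""
        self._check_fitted()
        preds = self.predict(X)
        truths = [
            np.stack([D.preprocess_label(m, self.input_size) for m in clip])
            for clip in _as_clips(y)]
        report = evaluate_masks(
            [m for clip in preds for m in clip],
            [m for clip in truths for m in clip])
        return report.per_image_mean.iou_vessel
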