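"""Dice-loss training with plain SGD.

The objective is L = (1 - dice) + rho * sum(w^2): a soft Dice loss over the
sigmoid probability map plus explicit L2 regularization of all trainable
parameters.  Optimization is stochastic gradient descent with a fixed
learning rate (optional classical momentum), seeded shuffling, and per-epoch
checkpoints.  The Dice gradient with respect to the probability map is
computed in closed form and seeded into the network's backward pass.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np

from .network import STNet, save_checkpoint


class TrainingDivergedError(RuntimeError):
    pass


@dataclasses.dataclass
class TrainingConfig:
    """Optimization hyperparameters.

    Defaults follow the full-scale recipe (fixed learning rate 2e-4, batch
    size 4, 100 epochs, SGD); desk-scale runs shrink ``epochs`` and typically
    raise the learning rate.  ``rho`` weighs the explicit L2 term;
    ``dice_smooth`` is the additive smoothing constant of the Dice ratio
    (making the empty-vs-empty case score 1).
    """

    learning_rate: float = 2e-4
    batch_size: int = 4
    epochs: int = 100
    rho: float = 1e-4
    momentum: float = 0.0
    seed: int = 0
    dice_smooth: float = 1.0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be > 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")


@dataclasses.dataclass
class LossBreakdown:
    dice_loss: float
    reg_loss: float

    @property
    def total(self) -> float:
        return self.dice_loss + self.reg_loss


def dice_coefficient(pred: np.ndarray, truth: np.ndarray,
                     smooth: float = 1.0) -> float:
    """Soft Dice overlap (2|X∩Y| + s) / (|X| + |Y| + s), in [0, 1].

    ``pred`` may be a probability map (soft intersection) or a binary mask.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = float((pred * truth).sum())
    denom = float(pred.sum() + truth.sum())
    return (2.0 * inter + smooth) / (denom + smooth)


def total_loss(pred: np.ndarray, truth: np.ndarray,
               weights: Iterable[np.ndarray], rho: float,
               smooth: float = 1.0) -> LossBreakdown:
    """Dice loss plus rho * sum of squared parameters."""
    if rho < 0:
        raise ValueError(f"rho must be >= 0, got {rho}")
    dice = dice_coefficient(pred, truth, smooth)
    reg = rho * sum(float((np.asarray(w) ** 2).sum()) for w in weights)
    return LossBreakdown(dice_loss=1.0 - dice, reg_loss=reg)


def _dice_grads(probs: np.ndarray, truth: np.ndarray,
                smooth: float) -> tuple:
    """Per-sample dice values and d(mean dice loss)/d(probs).

    probs, truth: (B, H, W).  Dice is computed per sample and averaged.
    """
    b = probs.shape[0]
    inter = (probs * truth).sum(axis=(1, 2))
    sums = probs.sum(axis=(1, 2)) + truth.sum(axis=(1, 2))
    num = 2.0 * inter + smooth
    den = sums + smooth
    dice = num / den
    # d dice_i/dp = (2*y*den - num)/den^2 ; loss = mean(1 - dice)
    grad = -(2.0 * truth * den[:, None, None] - num[:, None, None]) \
        / (den ** 2)[:, None, None] / b
    return dice, grad.astype(np.float32)


def train(model: STNet, x: np.ndarray, y: np.ndarray,
          config: TrainingConfig,
          out_dir: Optional[Union[str, Path]] = None) -> List[LossBreakdown]:
    """Train in place; returns the per-epoch mean loss log.

    ``x``: (M, 2N+1, H, W) windows; ``y``: (M, H, W) binary labels.  Windows
    from all clips are pooled and reshuffled every epoch (seeded).  A
    checkpoint is written per epoch plus ``best.npz`` at the lowest epoch
    loss when ``out_dir`` is given.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{x.shape[0]} windows but {y.shape[0]} labels")
    if x.shape[1] != model.config.depth:
        raise ValueError(
            f"window depth {x.shape[1]} != network depth {model.config.depth}")
    params = list(model.named_parameters())
    velocity = {name: np.zeros_like(p.data) for name, p in params} \
        if config.momentum else None
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: List[LossBreakdown] = []
    best = np.inf
    m = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(m)
        dice_sum, reg_sum, n_batches = 0.0, 0.0, 0
        for lo in range(0, m, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = x[idx], y[idx]
            model.zero_grad()
            pred = model(xb)                     # (B, 1, H, W)
            probs = pred.data[:, 0]
            dice, dgrad = _dice_grads(probs, yb, config.dice_smooth)
            if not np.all(np.isfinite(dice)):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            pred.backward(dgrad[:, None])
            reg = 0.0
            for name, p in params:
                reg += float((p.data.astype(np.float64) ** 2).sum())
                g = p.grad if p.grad is not None else 0.0
                g = g + 2.0 * config.rho * p.data
                if velocity is not None:
                    v = velocity[name]
                    v *= config.momentum
                    v -= config.learning_rate * g
                    p.data += v
                else:
                    p.data -= config.learning_rate * g
            dice_sum += float(1.0 - dice.mean())
            reg_sum += config.rho * reg
            n_batches += 1
        epoch_loss = LossBreakdown(dice_loss=dice_sum / n_batches,
                                   reg_loss=reg_sum / n_batches)
        log.append(epoch_loss)
        if out is not None:
            save_checkpoint(model, out / f"epoch_{epoch:03d}.npz")
            if epoch_loss.total < best:
                best = epoch_loss.total
                save_checkpoint(model, out / "best.npz")
    if out is not None:
        write_loss_log(log, out / "loss_log.csv")
    return log


def write_loss_log(log: List[LossBreakdown], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "dice_loss", "reg_loss", "total"])
        for i, row in enumerate(log):
            writer.writerow([i, f"{row.dice_loss:.8f}", f"{row.reg_loss:.8f}",
                             f"{row.total:.8f}"])
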