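"""Segmentation losses: cross-entropy, soft Dice, and their weighted hybrid.

Cross-entropy is the mean over all points of -log p at the true class, with
the probability floored at 1e-12 so the loss stays finite. The Dice loss is
computed per class on soft probabilities,

    dice_c = 1 - (2 * sum_i p_ic y_ic + eps) / (sum_i p_ic + sum_i y_ic + eps),

then macro-averaged over classes; the smoothing term eps guards the empty
class. The hybrid loss is the weighted sum

    hce = weight_ce * ce + weight_dice * dice,

with both weights defaulting to 0.5.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .config import LossConfig

__all__ = ["cross_entropy", "dice_loss", "hce_dice", "make_loss"]

_LOG_FLOOR = 1e-12


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    return np.eye(n_classes, dtype=np.float32)[labels]


def cross_entropy(probabilities: Tensor, labels: np.ndarray) -> Tensor:
    """Mean pointwise negative log-likelihood.

    probabilities: (..., N, C) tensor of per-point class probabilities whose
    rows sum to 1; labels: matching integer array.
    """
    n_classes = probabilities.shape[-1]
    y = _one_hot(labels, n_classes)
    if y.shape != probabilities.shape:
        raise ValueError(f"labels shape {np.shape(labels)} does not match "
                         f"probabilities {probabilities.shape}")
    logp = probabilities.clamp_min(_LOG_FLOOR).log()
    return -(logp * y).sum() * (1.0 / float(y[..., 0].size))


def dice_loss(probabilities: Tensor, labels: np.ndarray,
              epsilon: float = 1e-5) -> Tensor:
    """Soft Dice loss, macro-averaged over classes; value in [0, 1).

    For a batched (B, N, C) input the loss is computed per cloud and then
    averaged, so every cloud's overlap counts equally regardless of how many
    stem points it has — the point of Dice for imbalanced segmentation.
    """
    n_classes = probabilities.shape[-1]
    y = _one_hot(labels, n_classes)
    if probabilities.ndim == 2:
        probabilities = probabilities.reshape(1, -1, n_classes)
        y = y.reshape(1, -1, n_classes)
    if y.shape != tuple(probabilities.shape):
        raise ValueError("labels shape does not match probabilities")
    y_t = Tensor(y)
    intersection = (probabilities * y_t).sum(axis=1)     # (B, C)
    pred_sum = probabilities.sum(axis=1)
    target_sum = Tensor(y.sum(axis=1))
    dice = (intersection * 2.0 + epsilon) / (pred_sum + target_sum + epsilon)
    return (1.0 - dice).mean()


def hce_dice(probabilities: Tensor, labels: np.ndarray,
             config: LossConfig) -> Tensor:
    """weight_ce * cross_entropy + weight_dice * dice_loss."""
    config.validate()
    if config.weight_ce + config.weight_dice == 0:
        raise ValueError("at least one loss weight must be positive")
    total = None
    if config.weight_ce:
        total = config.weight_ce * cross_entropy(probabilities, labels)
    if config.weight_dice:
        term = config.weight_dice * dice_loss(probabilities, labels,
                                              config.epsilon)
        total = term if total is None else total + term
    return total


def make_loss(config: LossConfig):
    """Loss callable selected by ``config.name`` (ce | dice | hce)."""
    config.validate()
    if config.name == "ce":
        return lambda p, y: cross_entropy(p, y)
    if config.name == "dice":
        return lambda p, y: dice_loss(p, y, config.epsilon)
    if config.name == "hce":
        return lambda p, y: hce_dice(p, y, config)
    raise ValueError(f"unknown loss {config.name!r}")
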