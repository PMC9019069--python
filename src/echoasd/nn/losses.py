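"""Training objectives used across the three networks."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, where_positive

__all__ = [
    "cross_entropy",
    "kl_divergence",
    "binary_cross_entropy_with_logits",
    "sigmoid_focal_loss",
    "soft_dice_loss",
]


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``.

    ``logits`` may be (N, K) for classification or (N, K, H, W) for per-pixel
    labelling; ``labels`` holds class codes of matching spatial shape.
    """
    logp = logits.log_softmax(axis=1)
    labels = np.asarray(labels)
    onehot = np.zeros(logits.shape, dtype=np.float32)
    if logits.ndim == 2:
        onehot[np.arange(len(labels)), labels] = 1.0
    else:
        n, k = logits.shape[:2]
        idx = np.indices(labels.shape)
        onehot[idx[0], labels, idx[1], idx[2]] = 1.0
    denom = float(labels.size)
    return -(logp * Tensor(onehot)).sum() * (1.0 / denom)


def kl_divergence(p_logits: Tensor, q_logits: Tensor, temperature: float = 1.0) -> Tensor:
    """KL(softmax(p/T) || softmax(q/T)), averaged over rows.

    ``p`` is the reference (teacher) distribution; only ``q`` (student) needs
    gradients in distillation, but both paths are differentiable.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    t = 1.0 / temperature
    p = (p_logits * t).softmax(axis=1)
    logp = (p_logits * t).log_softmax(axis=1)
    logq = (q_logits * t).log_softmax(axis=1)
    n = p_logits.shape[0]
    return (p * (logp - logq)).sum() * (1.0 / n)


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray,
                                     reduction: str = "mean") -> Tensor:
    """Numerically stable BCE: max(x,0) - x*t + log(1 + exp(-|x|))."""
    t = Tensor(np.asarray(targets, dtype=np.float32))
    pos = logits.clip_min(0.0)
    absx = where_positive(logits.data >= 0, logits, -logits)
    loss = pos - logits * t + ((-absx).exp() + 1.0).log()
    if reduction == "mean":
        return loss.mean()
    if reduction == "sum":
        return loss.sum()
    return loss


def sigmoid_focal_loss(logits: Tensor, targets: np.ndarray, alpha: float = 0.25,
                       gamma: float = 2.0) -> Tensor:
    """Focal loss (summed); down-weights easy negatives in dense detection."""
    t = np.asarray(targets, dtype=np.float32)
    ce = binary_cross_entropy_with_logits(logits, t, reduction="none")
    p = logits.sigmoid()
    p_t = p * t + (1.0 - p) * (1.0 - t)
    alpha_t = alpha * t + (1.0 - alpha) * (1.0 - t)
    return (ce * (1.0 - p_t) ** gamma * alpha_t).sum()


def soft_dice_loss(logits: Tensor, labels: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 − mean per-class soft Dice on (N, K, H, W) logits vs integer labels."""
    probs = logits.softmax(axis=1)
    n, k = logits.shape[:2]
    onehot = np.zeros(logits.shape, dtype=np.float32)
    idx = np.indices(labels.shape)
    onehot[idx[0], labels, idx[1], idx[2]] = 1.0
    t = Tensor(onehot)
    inter = (probs * t).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + t.sum(axis=(0, 2, 3))
    dice = (inter * 2.0 + eps) / (denom + eps)
    return 1.0 - dice.mean()
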