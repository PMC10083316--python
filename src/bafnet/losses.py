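"""Compound segmentation objective: binary cross-entropy plus a soft-IoU
term, combined as alpha * L_bce + (1 - alpha) * L_iou with alpha = 0.5.

The soft-IoU term is -log of the soft Jaccard ratio
sum(g * p) / sum(g + p - g * p), a differentiable surrogate of
intersection-over-union summed over all pixels of the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossConfig", "bce_loss", "iou_loss", "total_loss"]


@dataclass
class LossConfig:
    """alpha: BCE weight in [0,1]; reduction: 'mean' or 'sum' (BCE only);
    epsilon: clamp for logarithms."""

    alpha: float = 0.5
    reduction: str = "mean"
    epsilon: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _pair(p, g):
    p = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    g = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=np.float64))
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {g.shape}")
    return p, g


def bce_loss(p, g, cfg: LossConfig | None = None) -> Tensor:
    """Binary cross-entropy between a probability map and a binary mask."""
    cfg = cfg or LossConfig()
    p, g = _pair(p, g)
    pc = p.clip(cfg.epsilon, 1.0 - cfg.epsilon)
    loss = -(g * pc.log() + (1.0 - g) * (1.0 - pc).log()).sum()
    if cfg.reduction == "mean":
        loss = loss * (1.0 / p.data.size)
    return loss


def iou_loss(p, g, cfg: LossConfig | None = None) -> Tensor:
    """-log soft-Jaccard over all pixels of the batch."""
    cfg = cfg or LossConfig()
    p, g = _pair(p, g)
    inter = (g * p).sum()
    union = (g + p - g * p).sum()
    if union.item() == 0.0:
        warnings.warn(
            "iou_loss: empty prediction and target; treating as perfect overlap",
            stacklevel=2,
        )
        return p.sum() * 0.0  # zero loss, still on the autodiff tape
    ratio = (inter / union).clip(cfg.epsilon, 1.0)
    return -ratio.log()


def total_loss(p, g, cfg: LossConfig | None = None) -> Tensor:
    """alpha-weighted sum of the BCE and soft-IoU terms."""
    cfg = cfg or LossConfig()
    return cfg.alpha * bce_loss(p, g, cfg) + (1.0 - cfg.alpha) * iou_loss(p, g, cfg)
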