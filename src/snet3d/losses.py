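"""Asymmetric (Tversky-style) overlap loss with deep supervision.

For each supervised head the soft confusion counts are formed from the
predicted foreground probabilities ``P`` and the binary ground truth ``G``::

    TP = sum(G * P)    FP = sum((1-G) * P)    FN = sum(G * (1-P))

and the Tversky index ``TI = TP / (TP + a*FP + b*FN)`` generalizes Dice
(``a = b = 0.5``). The defaults ``a = 0.3``, ``b = 0.7`` penalize false
negatives harder than false positives — recall is weighted over precision,
which is the right trade-off when the structure of interest is a few
voxels thin and a missed voxel costs more than a spurious one. The
training loss sums ``1 - TI`` over the supervised heads, so minimization
drives every head towards perfect overlap and the loss of an n-head model
lives in ``[0, n]``.

Soft (probability) counts keep the loss differentiable; masks are only
thresholded at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, tsum

__all__ = ["LossConfig", "SoftConfusion", "soft_confusion", "tversky_index",
           "deep_supervision_loss"]


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.3   # false-positive weight
    beta: float = 0.7    # false-negative weight
    smooth: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("need alpha, beta >= 0 and alpha + beta > 0")
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")


@dataclass(frozen=True)
class SoftConfusion:
    tp: float
    fp: float
    fn: float
    tn: float


def _check_pair(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs truth {g.shape}")


def soft_confusion(pred, truth) -> SoftConfusion:
    """Soft confusion counts of a probability map against a binary mask.

    Accepts arrays; for in-graph use see :func:`deep_supervision_loss`,
    which keeps the counts as autodiff nodes.
    """
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    _check_pair(p, g)
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    tp = float((g * p).sum())
    fp = float(((1 - g) * p).sum())
    fn = float((g * (1 - p)).sum())
    tn = float(((1 - g) * (1 - p)).sum())
    return SoftConfusion(tp, fp, fn, tn)


def tversky_index(c: SoftConfusion, cfg: LossConfig = LossConfig()) -> float:
    """TI = (TP + s) / (TP + a*FP + b*FN + s); 1 by convention when the
    denominator vanishes (empty foreground predicted as empty)."""
    denom = c.tp + cfg.alpha * c.fp + cfg.beta * c.fn + cfg.smooth
    if denom == 0.0:
        return 1.0
    return (c.tp + cfg.smooth) / denom


def _head_loss(p: Tensor, g: np.ndarray, cfg: LossConfig) -> Tensor:
    gt = Tensor(g.astype(np.float32))
    gc = Tensor((1.0 - g).astype(np.float32))
    tp = tsum(p * gt)
    fp = tsum(p * gc)
    fn = tsum(gt * (1.0 - p))
    ti = (tp + cfg.smooth) / (tp + cfg.alpha * fp + cfg.beta * fn + cfg.smooth)
    return 1.0 - ti


def deep_supervision_loss(preds: list[Tensor] | Tensor, truth: np.ndarray,
                          cfg: LossConfig = LossConfig()) -> Tensor:
    """Sum of ``1 - TI`` over the supervised heads (differentiable).

    ``preds`` is the list of per-head probability tensors at the ground
    truth's resolution (a single tensor is treated as one head).
    """
    if isinstance(preds, Tensor):
        preds = [preds]
    if not preds:
        raise ValueError("no prediction heads supplied")
    g = np.asarray(truth, dtype=np.float32)
    total: Tensor | None = None
    for p in preds:
        if p.shape != g.shape:
            raise ValueError(f"head shape {p.shape} does not match truth {g.shape}")
        term = _head_loss(p, g, cfg)
        total = term if total is None else total + term
    return total
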