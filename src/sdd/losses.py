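"""Occlusion-aware detection losses.

Total loss = CIoU attraction + alpha * RepGT + beta * RepBox, with the
repulsion terms passed through a piecewise Smooth_ln that is logarithmic up
to sigma and linear beyond it. Everything here is differentiable through the
:mod:`sdd.autograd` tensors, so boxes may come either as plain
:class:`~sdd.geometry.Box` objects (analysis) or as live tensors (training).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, cat, where
from .geometry import Box

__all__ = [
    "LossWeights", "AssignmentTable",
    "ciou_loss", "smooth_ln", "repgt_loss", "repbox_loss",
    "occlusion_loss", "classification_loss",
    "boxes_iou", "boxes_iog",
]


@dataclass
class LossWeights:
    alpha: float = 0.4
    beta: float = 0.6
    sigma_repgt: float = 0.5
    sigma_repbox: float = 0.5
    epsilon: float = 1e-7

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        for s in (self.sigma_repgt, self.sigma_repbox):
            if not (0.0 <= s < 1.0):
                raise ValueError("sigma must lie in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class AssignmentTable:
    """Per-positive bookkeeping: attraction GT, repulsion GT, and group id.

    `rep_idx` entries of -1 mean no repulsion candidate exists (e.g. a
    single-GT image). Group ids equal the assigned-GT index, partitioning
    positives into per-object groups for RepBox.
    """

    attr_idx: np.ndarray
    rep_idx: np.ndarray
    group_id: np.ndarray = None

    def __post_init__(self):
        self.attr_idx = np.asarray(self.attr_idx, dtype=int)
        self.rep_idx = np.asarray(self.rep_idx, dtype=int)
        if self.group_id is None:
            self.group_id = self.attr_idx.copy()
        self.group_id = np.asarray(self.group_id, dtype=int)
        if np.any(self.rep_idx == self.attr_idx):
            raise ValueError("repulsion GT must differ from the attraction GT")

    @property
    def n_pos(self) -> int:
        return len(self.attr_idx)


def _as_tensor(boxes) -> Tensor:
    if isinstance(boxes, Tensor):
        return boxes
    if isinstance(boxes, Box):
        return Tensor(boxes.as_array()[None, :])
    arr = np.array([b.as_array() if isinstance(b, Box) else np.asarray(b, dtype=float)
                    for b in boxes]) if isinstance(boxes, (list, tuple)) else np.asarray(boxes, dtype=float)
    arr = arr.reshape(-1, 4) if arr.size else np.zeros((0, 4))
    return Tensor(arr)


def boxes_iou(a: Tensor, b: Tensor, eps: float = 1e-9) -> Tensor:
    """Elementwise IoU of two (N,4) tensors of corner boxes."""
    x1 = a[:, 0].maximum(b[:, 0])
    y1 = a[:, 1].maximum(b[:, 1])
    x2 = a[:, 2].minimum(b[:, 2])
    y2 = a[:, 3].minimum(b[:, 3])
    inter = (x2 - x1).clamp_min(0.0) * (y2 - y1).clamp_min(0.0)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a + area_b - inter + eps)


def boxes_iog(p: Tensor, g: Tensor, eps: float = 1e-9) -> Tensor:
    """Elementwise intersection over ground-truth area of two (N,4) tensors."""
    x1 = p[:, 0].maximum(g[:, 0])
    y1 = p[:, 1].maximum(g[:, 1])
    x2 = p[:, 2].minimum(g[:, 2])
    y2 = p[:, 3].minimum(g[:, 3])
    inter = (x2 - x1).clamp_min(0.0) * (y2 - y1).clamp_min(0.0)
    area_g = (g[:, 2] - g[:, 0]) * (g[:, 3] - g[:, 1])
    return inter / (area_g + eps)


def ciou_loss(pred, gt, reduce: str = "mean") -> Tensor:
    """Complete-IoU loss: 1 - IoU + center-distance and aspect-ratio penalties."""
    p, g = _as_tensor(pred), _as_tensor(gt)
    wp = p.data[:, 2] - p.data[:, 0]
    hp = p.data[:, 3] - p.data[:, 1]
    wg = g.data[:, 2] - g.data[:, 0]
    hg = g.data[:, 3] - g.data[:, 1]
    if np.any(wp <= 0) or np.any(hp <= 0) or np.any(wg <= 0) or np.any(hg <= 0):
        raise ValueError("CIoU undefined for boxes with zero width or height")

    iou_v = boxes_iou(p, g)
    pcx = (p[:, 0] + p[:, 2]) * 0.5
    pcy = (p[:, 1] + p[:, 3]) * 0.5
    gcx = (g[:, 0] + g[:, 2]) * 0.5
    gcy = (g[:, 1] + g[:, 3]) * 0.5
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    # diagonal of the smallest enclosing rectangle
    cw = p[:, 2].maximum(g[:, 2]) - p[:, 0].minimum(g[:, 0])
    ch = p[:, 3].maximum(g[:, 3]) - p[:, 1].minimum(g[:, 1])
    c2 = cw ** 2 + ch ** 2 + 1e-12

    pw = p[:, 2] - p[:, 0]
    ph = p[:, 3] - p[:, 1]
    gw = g[:, 2] - g[:, 0]
    gh = g[:, 3] - g[:, 1]
    v = (4.0 / math.pi ** 2) * ((gw / gh).arctan() - (pw / ph).arctan()) ** 2
    omega = v / ((1.0 - iou_v) + v + 1e-12)
    loss = 1.0 - iou_v + rho2 / c2 + omega * v
    if reduce == "mean":
        return loss.mean()
    if reduce == "none":
        return loss
    raise ValueError(f"unknown reduce mode {reduce!r}")


def smooth_ln(x, sigma: float = 0.5) -> Tensor:
    """-ln(1-x) for x <= sigma, linear continuation beyond; defined on [0, 1)."""
    if not (0.0 <= sigma < 1.0):
        raise ValueError("sigma must lie in [0, 1)")
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
    if np.any(t.data >= 1.0) or np.any(t.data < 0.0):
        raise ValueError("smooth_ln argument must lie in [0, 1)")
    low = -((1.0 - t).log())
    high = (t - sigma) / (1.0 - sigma) - math.log(1.0 - sigma)
    return where(t.data <= sigma, low, high)


def repgt_loss(preds, gts, table: AssignmentTable, w: LossWeights | None = None) -> Tensor:
    """Mean Smooth_ln(IoG(P, G_Rep)) over positives; no-candidate positives add 0."""
    w = w or LossWeights()
    p = _as_tensor(preds)
    n_pos = p.shape[0]
    if n_pos == 0:
        warnings.warn("RepGT over an empty positive set is 0", stacklevel=2)
        return Tensor(np.asarray(0.0))
    has_rep = table.rep_idx >= 0
    if not np.any(has_rep):
        return Tensor(np.asarray(0.0))
    g = _as_tensor(gts)
    sel_p = p[np.flatnonzero(has_rep)]
    sel_g = g[table.rep_idx[has_rep]]
    # cap just below 1: a full cover otherwise makes the log term infinite
    iog_v = boxes_iog(sel_p, sel_g).minimum(1.0 - 1e-3)
    return smooth_ln(iog_v, w.sigma_repgt).sum() / float(n_pos)


def repbox_loss(preds, table: AssignmentTable, w: LossWeights | None = None) -> Tensor:
    """Smooth_ln(IoU) summed over unordered cross-group prediction pairs,
    normalized by the count of overlapping pairs plus epsilon."""
    w = w or LossWeights()
    p = _as_tensor(preds)
    n = p.shape[0]
    gid = table.group_id
    ii, jj = np.triu_indices(n, k=1)
    mask = gid[ii] != gid[jj]
    ii, jj = ii[mask], jj[mask]
    if len(ii) == 0:
        return Tensor(np.asarray(0.0))
    iou_v = boxes_iou(p[ii], p[jj]).minimum(1.0 - 1e-3)
    denom = float((iou_v.data > 0).sum()) + w.epsilon
    return smooth_ln(iou_v, w.sigma_repbox).sum() / denom


def occlusion_loss(preds, gts, table: AssignmentTable,
                   w: LossWeights | None = None) -> tuple[Tensor, dict]:
    """Composite loss: mean CIoU + alpha * RepGT + beta * RepBox."""
    w = w or LossWeights()
    p, g = _as_tensor(preds), _as_tensor(gts)
    attraction = ciou_loss(p, g[table.attr_idx])
    rep_gt = repgt_loss(p, g, table, w)
    rep_box = repbox_loss(p, table, w)
    total = attraction + w.alpha * rep_gt + w.beta * rep_box
    return total, {"ciou": attraction, "repgt": rep_gt, "repbox": rep_box}


def classification_loss(logits, targets) -> Tensor:
    """Mean binary cross-entropy on sigmoid scores, from raw logits."""
    x = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits, dtype=float))
    t = np.asarray(targets.data if isinstance(targets, Tensor) else targets, dtype=float)
    if x.shape != t.shape:
        raise ValueError(f"logits shape {x.shape} != targets shape {t.shape}")
    # BCE-with-logits: softplus(x) - x*t, stable for both signs
    return (x.softplus() - x * Tensor(t)).mean()
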