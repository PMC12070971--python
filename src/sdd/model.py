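"""Detector assembly: backbone (wavelet-enhanced downsampling + C2f + SPPF),
PAN neck with attention fusion of stride-4 detail features, shared detection
head, target assignment, box decoding, NMS, training loop, and parameter /
FLOP accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, cat, flop_counter, maxpool2d, upsample2x
from .config import ModelConfig, RunConfig
from .ls_head import DecoupledHead, HeadConfig, LSHead
from .losses import (AssignmentTable, LossWeights, boxes_iou, ciou_loss,
                     classification_loss, occlusion_loss)
from .nn import AdamW, Conv2d, ConvGN, Module, Sequential
from .opam import OPAM
from .wavelet import WEConv

__all__ = [
    "Detector", "DetectionSet", "build_model", "count_params", "estimate_flops",
    "assign_targets", "decode_levels", "nms", "decode_and_nms",
    "train_loop", "save_checkpoint", "load_checkpoint",
]

STRIDES = (8, 16, 32)


# --------------------------------------------------------------------- blocks
class Bottleneck(Module):
    def __init__(self, rng, c: int, shortcut: bool = True):
        self.cv1 = ConvGN(rng, c, c, kernel=3)
        self.cv2 = ConvGN(rng, c, c, kernel=3)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(Module):
    """Split/bottleneck/concat cross-stage block."""

    def __init__(self, rng, c_in: int, c_out: int, n: int = 1, shortcut: bool = True):
        self.c = c_out // 2
        self.cv1 = ConvGN(rng, c_in, c_out, kernel=1)
        self.cv2 = ConvGN(rng, (2 + n) * self.c, c_out, kernel=1)
        self.blocks = [Bottleneck(rng, self.c, shortcut) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(cat(outs, axis=1))


class SPPF(Module):
    """Triple 5x5 max-pool pyramid with concat fusion."""

    def __init__(self, rng, c_in: int, c_out: int):
        c_mid = c_in // 2
        self.cv1 = ConvGN(rng, c_in, c_mid, kernel=1)
        self.cv2 = ConvGN(rng, 4 * c_mid, c_out, kernel=1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = maxpool2d(y, 5, stride=1, padding=2)
        p2 = maxpool2d(p1, 5, stride=1, padding=2)
        p3 = maxpool2d(p2, 5, stride=1, padding=2)
        return self.cv2(cat([y, p1, p2, p3], axis=1))


def make_divisible(v: float, divisor: int = 8) -> int:
    return max(divisor, int(round(v / divisor) * divisor))


# ------------------------------------------------------------------- detector
@dataclass
class DetectionSet:
    boxes: np.ndarray          # (K,4) pixel corners, clipped
    scores: np.ndarray         # (K,) descending
    class_ids: np.ndarray      # (K,)

    def __len__(self) -> int:
        return len(self.scores)


class Detector(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        depth, width, max_ch = cfg.scales
        base = [64, 128, 256, 512, 1024]
        ch = [make_divisible(min(c, max_ch) * width) for c in base]
        n1 = max(1, round(3 * depth))
        n2 = max(1, round(6 * depth))
        self.cfg = cfg
        self.channels = ch
        c1, c2, c3, c4, c5 = ch

        def down(c_in, c_out, stage):
            if cfg.use_weconv and stage in cfg.weconv.stages:
                return WEConv(rng, c_in, c_out, levels=cfg.weconv.levels,
                              kernel=cfg.weconv.kernel)
            return ConvGN(rng, c_in, c_out, kernel=3, stride=2)

        # backbone
        self.stem = ConvGN(rng, 3, c1, kernel=3, stride=2)          # -> C1 (s2)
        self.down2, self.c2f2 = down(c1, c2, 2), C2f(rng, c2, c2, n1)
        self.down3, self.c2f3 = down(c2, c3, 3), C2f(rng, c3, c3, n2)
        self.down4, self.c2f4 = down(c3, c4, 4), C2f(rng, c4, c4, n2)
        self.down5, self.c2f5 = down(c4, c5, 5), C2f(rng, c5, c5, n1)
        self.sppf = SPPF(rng, c5, c5)

        # top-down neck
        self.td1 = C2f(rng, c5 + c4, c4, n1, shortcut=False)
        self.td2 = C2f(rng, c4 + c3, c3, n1, shortcut=False)
        if cfg.use_opam:
            self.opam = OPAM(rng, c2, c3, c3, reduction=cfg.opam.reduction,
                             shared_gate=cfg.opam.shared_gate,
                             gate_kernel=cfg.opam.gate_kernel)
        else:
            self.opam = None
        # bottom-up neck
        self.bu1 = ConvGN(rng, c3, c3, kernel=3, stride=2)
        self.bu2 = C2f(rng, c3 + c4, c4, n1, shortcut=False)
        self.bu3 = ConvGN(rng, c4, c4, kernel=3, stride=2)
        self.bu4 = C2f(rng, c4 + c5, c5, n1, shortcut=False)

        head_cfg = HeadConfig(middle_channel=cfg.head.middle_channel,
                              reg_max=cfg.head.reg_max, use_dfl=cfg.head.use_dfl)
        head_cls = LSHead if cfg.use_ls_head else DecoupledHead
        self.head = head_cls(rng, [c3, c4, c5], head_cfg)
        self.head_cfg = head_cfg

    def forward(self, x) -> list[tuple[Tensor, Tensor]]:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        c1 = self.stem(x)
        c2 = self.c2f2(self.down2(c1))
        c3 = self.c2f3(self.down3(c2))
        c4 = self.c2f4(self.down4(c3))
        c5 = self.sppf(self.c2f5(self.down5(c4)))

        f4 = self.td1(cat([upsample2x(c5), c4], axis=1))
        f3 = self.td2(cat([upsample2x(f4), c3], axis=1))
        p3 = self.opam(c2, f3) if self.opam is not None else f3
        p4 = self.bu2(cat([self.bu1(p3), f4], axis=1))
        p5 = self.bu4(cat([self.bu3(p4), c5], axis=1))
        return self.head(p3, p4, p5)


def build_model(cfg: ModelConfig | RunConfig, seed: int = 0) -> Detector:
    if isinstance(cfg, RunConfig):
        cfg = cfg.model
    return Detector(cfg, seed=seed)


def count_params(model: Module) -> float:
    """Total learned scalars in millions, rounded to two decimals."""
    return round(model.num_params() / 1e6, 2)


def estimate_flops(model: Detector, input_size: int | None = None) -> float:
    """GFLOPs of a forward pass (2 x multiply-accumulates, conv layers)."""
    size = input_size or model.cfg.input_size
    x = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    with flop_counter() as fc:
        model(x)
    return fc.total / 1e9


# ------------------------------------------------------------------ decoding
def anchor_grid(size: int, strides=STRIDES) -> list[np.ndarray]:
    """Per-level (H*W, 2) anchor-point centers in pixels."""
    grids = []
    for s in strides:
        n = size // s
        xs = (np.arange(n) + 0.5) * s
        gx, gy = np.meshgrid(xs, xs)
        grids.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
    return grids


def decode_levels(outputs, size: int, head_cfg: HeadConfig,
                  differentiable: bool = False):
    """Decode head outputs to per-anchor logits and corner boxes.

    Returns (cls_logits, boxes, anchor_points, anchor_strides); the first two
    are Tensors when `differentiable`, else plain arrays. Boxes are decoded
    from per-side distances (DFL bin expectation when enabled) scaled by the
    level stride.
    """
    cls_parts, box_parts = [], []
    points, strides_v = [], []
    r = head_cfg.reg_max
    for (cls, reg), s in zip(outputs, STRIDES):
        n, _, h, w = cls.shape
        a = h * w
        cls_flat = cls.reshape(n, head_cfg.num_classes, a).transpose(0, 2, 1)
        if head_cfg.use_dfl:
            logits = reg.reshape(n, 4, r, a)
            prob = logits.softmax(axis=2) if differentiable else _np_softmax(logits.data, 2)
            bins = np.arange(r, dtype=np.float32).reshape(1, 1, r, 1)
            dist = (prob * Tensor(bins)).sum(axis=2) if differentiable else (prob * bins).sum(axis=2)
        else:
            # clamp at a hundredth of a stride so decoded boxes keep positive extent
            dist = reg.reshape(n, 4, a)
            dist = dist.maximum(Tensor(np.full(1, 1e-2, np.float32))) if differentiable \
                else np.maximum(dist.data, 1e-2)
        dist = dist * float(s)
        xs = (np.arange(w) + 0.5) * s
        ys = (np.arange(h) + 0.5) * s
        gx, gy = np.meshgrid(xs, ys)
        px = gx.ravel().astype(np.float32)
        py = gy.ravel().astype(np.float32)
        if differentiable:
            l, t, rr, b = dist[:, 0], dist[:, 1], dist[:, 2], dist[:, 3]
            box = [Tensor(px) - l, Tensor(py) - t, Tensor(px) + rr, Tensor(py) + b]
            box = cat([v.reshape(n, a, 1) for v in box], axis=2)
        else:
            d = dist
            box = np.stack([px - d[:, 0], py - d[:, 1], px + d[:, 2], py + d[:, 3]], axis=2)
        cls_parts.append(cls_flat)
        box_parts.append(box)
        points.append(np.stack([px, py], axis=1))
        strides_v.append(np.full(a, s, dtype=np.float32))
    if differentiable:
        cls_all = cat(cls_parts, axis=1)
        box_all = cat(box_parts, axis=1)
    else:
        cls_all = np.concatenate([c.data for c in cls_parts], axis=1)
        box_all = np.concatenate(box_parts, axis=1)
    return cls_all, box_all, np.concatenate(points), np.concatenate(strides_v)


def _np_softmax(x: np.ndarray, axis: int) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


# ----------------------------------------------------------------- assignment
def _pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(N,4) x (M,4) -> (N,M) IoU matrix."""
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(area_a[:, None] + area_b[None, :] - inter, 1e-12)


def assign_targets(gt_boxes: np.ndarray, scores: np.ndarray, pred_boxes: np.ndarray,
                   points: np.ndarray, topk: int = 10,
                   alpha: float = 0.5, beta: float = 6.0):
    """Task-aligned top-k assignment.

    alignment = score^alpha * IoU(pred, gt)^beta, restricted to anchors whose
    point lies inside the GT; the top-k aligned candidates per GT become
    positives, conflicts resolved by the larger alignment. A vanishing
    alignment falls back to center proximity so assignment is well defined at
    initialization. Returns (pos_anchor_idx, AssignmentTable, iou_matrix).
    """
    n_anchor = len(points)
    m = len(gt_boxes)
    if m == 0:
        return np.empty(0, int), AssignmentTable(np.empty(0, int), np.empty(0, int)), \
            np.zeros((n_anchor, 0))
    inside = ((points[:, 0:1] > gt_boxes[None, :, 0]) & (points[:, 0:1] < gt_boxes[None, :, 2])
              & (points[:, 1:2] > gt_boxes[None, :, 1]) & (points[:, 1:2] < gt_boxes[None, :, 3]))
    iou_m = _pairwise_iou(pred_boxes, gt_boxes)
    gcx = (gt_boxes[:, 0] + gt_boxes[:, 2]) / 2
    gcy = (gt_boxes[:, 1] + gt_boxes[:, 3]) / 2
    dist = np.hypot(points[:, 0:1] - gcx[None], points[:, 1:2] - gcy[None])
    align = (np.clip(scores, 1e-9, 1)[:, None] ** alpha) * (iou_m ** beta)
    align = align + 1e-9 / (1.0 + dist)  # deterministic proximity tiebreak
    align = np.where(inside, align, -1.0)

    chosen_gt = np.full(n_anchor, -1, int)
    chosen_align = np.full(n_anchor, -np.inf)
    for j in range(m):
        cand = np.flatnonzero(align[:, j] > 0)
        if len(cand) == 0:
            continue
        top = cand[np.argsort(-align[cand, j], kind="stable")[:topk]]
        for a_idx in top:
            if align[a_idx, j] > chosen_align[a_idx]:
                chosen_align[a_idx] = align[a_idx, j]
                chosen_gt[a_idx] = j
    pos = np.flatnonzero(chosen_gt >= 0)
    attr = chosen_gt[pos]
    rep = np.full(len(pos), -1, int)
    if m > 1:
        iou_pos = iou_m[pos].copy()
        iou_pos[np.arange(len(pos)), attr] = -1.0
        best = iou_pos.argmax(axis=1)
        rep = np.where(iou_pos[np.arange(len(pos)), best] > 0, best, -1)
    return pos, AssignmentTable(attr, rep), iou_m


# ----------------------------------------------------------------------- NMS
def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy class-agnostic NMS; returns kept indices in score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        rest = order[~suppressed[order]]
        ious = _pairwise_iou(boxes[i:i + 1], boxes[rest])[0]
        suppressed[rest[ious > iou_thr]] = True
        suppressed[i] = False  # keep self
    return np.array(keep, int)


def decode_and_nms(outputs, size: int, head_cfg: HeadConfig,
                   conf_thr: float = 1e-3, iou_thr: float = 0.65) -> list[DetectionSet]:
    """Decode head outputs for a batch and run confidence filter + NMS."""
    cls_all, box_all, _, _ = decode_levels(outputs, size, head_cfg)
    results = []
    for n in range(cls_all.shape[0]):
        scores = 1.0 / (1.0 + np.exp(-cls_all[n, :, 0]))
        mask = scores >= conf_thr
        b, s = box_all[n][mask], scores[mask]
        keep = nms(b, s, iou_thr) if len(s) else np.empty(0, int)
        b, s = b[keep], s[keep]
        order = np.argsort(-s, kind="stable")
        b = np.clip(b[order], 0, size)
        results.append(DetectionSet(b, s[order], np.zeros(len(order), int)))
    return results


# ------------------------------------------------------------------- training
def _dfl_targets_loss(reg_logits: Tensor, pos_idx: np.ndarray, gt: np.ndarray,
                      points: np.ndarray, strides_v: np.ndarray, reg_max: int) -> Tensor:
    """Distribution-focal regression: cross-entropy against the two bins
    bracketing the true per-side distance (in stride units)."""
    px, py = points[pos_idx, 0], points[pos_idx, 1]
    s = strides_v[pos_idx]
    target = np.stack([px - gt[:, 0], py - gt[:, 1], gt[:, 2] - px, gt[:, 3] - py], axis=1) / s[:, None]
    target = np.clip(target, 0, reg_max - 1 - 1e-3)
    lo = np.floor(target).astype(int)
    hi = lo + 1
    w_hi = target - lo
    w_lo = 1.0 - w_hi
    logp = (reg_logits.softmax(axis=2) + 1e-9).log()   # (P,4,R)
    rows = np.arange(len(pos_idx))[:, None]
    cols = np.arange(4)[None, :]
    ll = logp[rows, cols, lo] * Tensor(w_lo) + logp[rows, cols, hi] * Tensor(w_hi)
    return -(ll.mean())


def compute_loss(model: Detector, images: np.ndarray, gt_list: list[np.ndarray],
                 run_cfg: RunConfig) -> tuple[Tensor, dict]:
    """Forward a batch and assemble the composite training loss."""
    use_rep = run_cfg.loss.repulsion
    lw = LossWeights(alpha=run_cfg.loss.alpha if use_rep else 0.0,
                     beta=run_cfg.loss.beta if use_rep else 0.0,
                     sigma_repgt=run_cfg.loss.sigma_repgt,
                     sigma_repbox=run_cfg.loss.sigma_repbox,
                     epsilon=run_cfg.loss.epsilon)
    size = images.shape[-1]
    outputs = model(images)
    head_cfg = model.head_cfg
    cls_all, box_all, points, strides_v = decode_levels(
        outputs, size, head_cfg, differentiable=True)

    zero = Tensor(np.asarray(0.0, dtype=np.float32))
    total_box, total_rep_gt, total_rep_box, total_dfl = zero, zero, zero, zero
    cls_terms = []
    n_img = images.shape[0]
    n_pos_total = 0
    for n in range(n_img):
        gt = gt_list[n]
        scores_np = 1.0 / (1.0 + np.exp(-cls_all.data[n, :, 0]))
        pos, table, iou_m = assign_targets(gt, scores_np, box_all.data[n], points)
        cls_target = np.zeros(len(points), dtype=np.float32)
        if len(pos):
            # quality-aware soft targets: score should track localization quality
            q = iou_m[pos, table.attr_idx]
            cls_target[pos] = np.clip(np.maximum(q, 0.2), 0.0, 1.0)
        cls_terms.append(classification_loss(cls_all[n, :, 0], cls_target))
        if len(pos) == 0:
            continue
        n_pos_total += len(pos)
        pred_pos = box_all[n][pos]
        gt_t = Tensor(gt.astype(np.float32))
        box_total, comps = occlusion_loss(pred_pos, gt_t, table, lw)
        total_box = total_box + comps["ciou"] * len(pos)
        total_rep_gt = total_rep_gt + comps["repgt"] * len(pos)
        total_rep_box = total_rep_box + comps["repbox"] * len(pos)
        if head_cfg.use_dfl and run_cfg.loss.use_dfl_loss:
            reg_logits = _level_logits(outputs, head_cfg)[n][pos]
            total_dfl = total_dfl + _dfl_targets_loss(
                reg_logits, pos, gt[table.attr_idx], points, strides_v,
                head_cfg.reg_max) * len(pos)

    cls_loss = cls_terms[0]
    for t in cls_terms[1:]:
        cls_loss = cls_loss + t
    cls_loss = cls_loss * (1.0 / n_img)
    denom = max(n_pos_total, 1)
    ciou = total_box * (1.0 / denom)
    rep_gt = total_rep_gt * (1.0 / denom)
    rep_box = total_rep_box * (1.0 / denom)
    dfl = total_dfl * (1.0 / denom)
    total = (ciou + lw.alpha * rep_gt + lw.beta * rep_box
             + run_cfg.loss.cls_weight * cls_loss
             + run_cfg.loss.dfl_weight * dfl)
    comps = {"ciou": ciou.item(), "repgt": rep_gt.item(), "repbox": rep_box.item(),
             "cls": cls_loss.item(), "dfl": dfl.item(), "n_pos": n_pos_total}
    return total, comps


def _level_logits(outputs, head_cfg: HeadConfig) -> Tensor:
    """Concatenated per-anchor DFL logits, shape (N, A, 4, reg_max)."""
    parts = []
    r = head_cfg.reg_max
    for cls, reg in outputs:
        n, _, h, w = reg.shape
        parts.append(reg.reshape(n, 4, r, h * w).transpose(0, 3, 1, 2))
    return cat(parts, axis=1)


def train_loop(dataset, run_cfg: RunConfig, iterations: int | None = None,
               model: Detector | None = None, log=None) -> tuple[Detector, list[dict]]:
    """Iterate forward/loss/AdamW steps over a small in-memory dataset.

    `dataset` is a list of (image HWC uint8-or-float array, gt (M,4) pixel
    corner boxes). Deterministic given run_cfg.train.seed.
    """
    tcfg = run_cfg.train
    rng = np.random.default_rng(tcfg.seed)
    if model is None:
        model = build_model(run_cfg.model, seed=tcfg.seed)
    opt = AdamW(model.parameters(), lr=tcfg.lr, betas=(tcfg.momentum, 0.999),
                weight_decay=tcfg.weight_decay)
    images = np.stack([np.transpose(np.asarray(im, dtype=np.float32) / 255.0, (2, 0, 1))
                       for im, _ in dataset])
    gts = [np.asarray(g, dtype=np.float32) for _, g in dataset]
    batch = min(tcfg.batch, len(dataset))
    steps_per_epoch = max(1, len(dataset) // batch)
    n_steps = iterations if iterations is not None else tcfg.epochs * steps_per_epoch
    warmup = tcfg.warmup_epochs * steps_per_epoch
    history = []
    order = rng.permutation(len(dataset))
    cursor = 0
    for step in range(n_steps):
        if cursor + batch > len(dataset):
            order = rng.permutation(len(dataset))
            cursor = 0
        idx = order[cursor:cursor + batch]
        cursor += batch
        lr_scale = (step + 1) / warmup if warmup and step < warmup else 1.0
        opt.lr = tcfg.lr * lr_scale
        total, comps = compute_loss(model, images[idx], [gts[i] for i in idx], run_cfg)
        if not np.isfinite(total.item()):
            raise RuntimeError(f"non-finite loss at step {step}: {comps}")
        opt.zero_grad()
        total.backward()
        opt.step()
        comps["step"] = step
        comps["total"] = total.item()
        comps["lr"] = opt.lr
        history.append(comps)
        if log is not None:
            log(comps)
    return model, history


def save_checkpoint(model: Detector, run_cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    meta = {"config": run_cfg.model_dump(), "seed": run_cfg.train.seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> tuple[Detector, RunConfig]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    run_cfg = RunConfig.model_validate(meta["config"])
    model = build_model(run_cfg.model, seed=meta.get("seed", 0))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, run_cfg
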