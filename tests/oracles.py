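"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written by a different route than the
library code: rasterized counting instead of exact sweeps, brute-force
enumeration instead of vectorized matching, and a COCO-style accumulate
evaluator instead of the package's curve-based one.
"""

from __future__ import annotations

import numpy as np


# ------------------------------------------------------------- rasterization
def raster_union_or(target, others, resolution: int = 1) -> float:
    """Overlap ratio by counting covered cells of a unit (or finer) grid.

    Exact for integer-coordinate boxes at resolution 1.
    """
    tx1, ty1, tx2, ty2 = [int(round(v * resolution)) for v in
                          (target.x1, target.y1, target.x2, target.y2)]
    if tx2 <= tx1 or ty2 <= ty1:
        raise ValueError("zero-area target")
    grid = np.zeros((tx2 - tx1, ty2 - ty1), dtype=bool)
    for o in others:
        ox1 = max(tx1, int(round(o.x1 * resolution)))
        oy1 = max(ty1, int(round(o.y1 * resolution)))
        ox2 = min(tx2, int(round(o.x2 * resolution)))
        oy2 = min(ty2, int(round(o.y2 * resolution)))
        if ox2 > ox1 and oy2 > oy1:
            grid[ox1 - tx1:ox2 - tx1, oy1 - ty1:oy2 - ty1] = True
    return grid.sum() / grid.size


def raster_iou(a, b, canvas: int = 64) -> float:
    ga = np.zeros((canvas, canvas), bool)
    gb = np.zeros((canvas, canvas), bool)
    ga[int(a.x1):int(a.x2), int(a.y1):int(a.y2)] = True
    gb[int(b.x1):int(b.x2), int(b.y1):int(b.y2)] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union if union else 0.0


def raster_iog(p, g, canvas: int = 64) -> float:
    gp = np.zeros((canvas, canvas), bool)
    gg = np.zeros((canvas, canvas), bool)
    gp[int(p.x1):int(p.x2), int(p.y1):int(p.y2)] = True
    gg[int(g.x1):int(g.x2), int(g.y1):int(g.y2)] = True
    return (gp & gg).sum() / gg.sum()


# ------------------------------------------------------------------ matching
def brute_force_nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    """O(n^2) greedy NMS, re-deriving IoU per pair with scalar arithmetic."""
    idx = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    kept: list[int] = []
    for i in idx:
        ok = True
        for j in kept:
            xx1 = max(boxes[i][0], boxes[j][0])
            yy1 = max(boxes[i][1], boxes[j][1])
            xx2 = min(boxes[i][2], boxes[j][2])
            yy2 = min(boxes[i][3], boxes[j][3])
            inter = max(0.0, xx2 - xx1) * max(0.0, yy2 - yy1)
            ai = (boxes[i][2] - boxes[i][0]) * (boxes[i][3] - boxes[i][1])
            aj = (boxes[j][2] - boxes[j][0]) * (boxes[j][3] - boxes[j][1])
            if inter / max(ai + aj - inter, 1e-12) > iou_thr:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


def greedy_match(det_boxes, det_scores, gt_boxes, thr):
    """Scalar re-implementation of score-order greedy matching."""
    order = sorted(range(len(det_scores)), key=lambda i: (-det_scores[i], i))
    taken = set()
    tp = [False] * len(det_boxes)
    for i in order:
        best_j, best_iou = -1, -1.0
        for j in range(len(gt_boxes)):
            if j in taken:
                continue
            a, g = det_boxes[i], gt_boxes[j]
            xx1, yy1 = max(a[0], g[0]), max(a[1], g[1])
            xx2, yy2 = min(a[2], g[2]), min(a[3], g[3])
            inter = max(0.0, xx2 - xx1) * max(0.0, yy2 - yy1)
            ua = ((a[2] - a[0]) * (a[3] - a[1]) + (g[2] - g[0]) * (g[3] - g[1]) - inter)
            iou = inter / max(ua, 1e-12)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= thr:
            tp[i] = True
            taken.add(best_j)
    fn = len(gt_boxes) - len(taken)
    return tp, fn


# --------------------------------------------------- COCO-style reference AP
def reference_ap(dets_by_image: dict, gts_by_image: dict, thr: float) -> float:
    """Accumulate-style AP at one IoU threshold on the 101-point recall grid.

    Mirrors the pycocotools structure: per-image dtm arrays, concatenated in
    global score order, precision interpolated right-to-left.
    """
    all_scores, all_matched = [], []
    n_gt = 0
    for image_id, gts in gts_by_image.items():
        n_gt += len(gts)
        det = dets_by_image.get(image_id)
        if det is None:
            continue
        boxes, scores = det
        tp, _ = greedy_match(np.asarray(boxes), np.asarray(scores), np.asarray(gts), thr)
        all_scores.extend(np.asarray(scores).tolist())
        all_matched.extend(tp)
    if n_gt == 0:
        return float("nan")
    if not all_scores:
        return 0.0
    order = sorted(range(len(all_scores)), key=lambda i: (-all_scores[i], i))
    matched = np.array([all_matched[i] for i in order])
    tps = np.cumsum(matched)
    fps = np.cumsum(~matched)
    rc = tps / n_gt
    pr = tps / np.maximum(tps + fps, np.finfo(float).eps)
    # right-to-left envelope, exactly as COCOeval.accumulate does
    pr = pr.tolist()
    for i in range(len(pr) - 1, 0, -1):
        if pr[i] > pr[i - 1]:
            pr[i - 1] = pr[i]
    rec_thrs = np.linspace(0.0, 1.0, 101)
    inds = np.searchsorted(rc, rec_thrs, side="left")
    q = np.zeros(len(rec_thrs))
    for ri, pi in enumerate(inds):
        if pi < len(pr):
            q[ri] = pr[pi]
    return float(q.mean())


def reference_ap_range(dets_by_image: dict, gts_by_image: dict):
    thrs = [0.5 + 0.05 * i for i in range(10)]
    aps = [reference_ap(dets_by_image, gts_by_image, t) for t in thrs]
    return {"ap50": aps[0], "ap75": aps[5], "ap_range": float(np.mean(aps)), "all": aps}
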