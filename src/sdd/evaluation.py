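"""Precision/recall/AP computation with COCO-style thresholds.

AP is the area under the interpolated precision-recall curve, sampled on the
101-point recall grid; AP50:95 averages the ten IoU thresholds 0.50, 0.55,
..., 0.95. Matching is greedy in score order with each ground truth matched
at most once. Reports can additionally be stratified by the dense-occlusion
subset rule (image OR > 0.5 and more than 40 objects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AnnotatedImage, Box, dense_subset, image_or

__all__ = ["PRCurve", "APResult", "match_detections", "pr_curve",
           "average_precision", "ap_range", "evaluate_detections"]

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class PRCurve:
    precision: np.ndarray   # cumulative precision, score-descending order
    recall: np.ndarray      # cumulative recall, non-decreasing
    iou_threshold: float
    n_gt: int


@dataclass
class APResult:
    ap50: float
    ap75: float
    ap_range: float
    per_threshold: dict[float, float]


def _box_array(boxes) -> np.ndarray:
    if len(boxes) == 0:
        return np.zeros((0, 4))
    return np.array([b.as_array() if isinstance(b, Box) else np.asarray(b, float)
                     for b in boxes])


def match_detections(det_boxes, det_scores, gt_boxes, iou_thr: float):
    """Greedy score-order matching within one image.

    Detections are visited in descending score order (stable); the returned
    (tp flags, fp flags, fn count) are aligned with the *input* order. Each
    GT matches at most one detection; a detection is TP iff its best
    *unmatched* GT has IoU >= iou_thr.
    """
    db = _box_array(det_boxes)
    gb = _box_array(gt_boxes)
    order = np.argsort(-np.asarray(det_scores), kind="stable")
    tp = np.zeros(len(db), bool)
    matched = np.zeros(len(gb), bool)
    for i in order:
        if len(gb) == 0:
            break
        x1 = np.maximum(db[i, 0], gb[:, 0])
        y1 = np.maximum(db[i, 1], gb[:, 1])
        x2 = np.minimum(db[i, 2], gb[:, 2])
        y2 = np.minimum(db[i, 3], gb[:, 3])
        inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
        area_d = (db[i, 2] - db[i, 0]) * (db[i, 3] - db[i, 1])
        area_g = (gb[:, 2] - gb[:, 0]) * (gb[:, 3] - gb[:, 1])
        ious = inter / np.maximum(area_d + area_g - inter, 1e-12)
        ious = np.where(matched, -1.0, ious)
        j = int(ious.argmax()) if len(ious) else -1
        if j >= 0 and ious[j] >= iou_thr:
            tp[i] = True
            matched[j] = True
    fp = ~tp
    fn = int((~matched).sum())
    return tp, fp, fn


def pr_curve(dets_by_image: dict, gts_by_image: dict, iou_thr: float) -> PRCurve:
    """Dataset-level PR curve: match per image, accumulate in global score order."""
    scores, flags = [], []
    n_gt = 0
    for image_id, gts in gts_by_image.items():
        n_gt += len(gts)
        det = dets_by_image.get(image_id)
        if det is None or len(det[1]) == 0:
            continue
        boxes, s = det
        tp, _, _ = match_detections(boxes, s, gts, iou_thr)
        scores.append(np.asarray(s, float))
        flags.append(tp)
    if scores:
        scores = np.concatenate(scores)
        flags = np.concatenate(flags)
        order = np.argsort(-scores, kind="stable")
        flags = flags[order]
        tp_cum = np.cumsum(flags)
        fp_cum = np.cumsum(~flags)
        precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
        recall = tp_cum / n_gt if n_gt else np.zeros_like(tp_cum, float)
    else:
        precision = np.zeros(0)
        recall = np.zeros(0)
    return PRCurve(precision, recall, iou_thr, n_gt)


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope on the 101-point recall grid."""
    if curve.n_gt == 0:
        return float("nan")
    if len(curve.precision) == 0:
        return 0.0
    # precision envelope: running max from the right
    env = np.maximum.accumulate(curve.precision[::-1])[::-1]
    idx = np.searchsorted(curve.recall, RECALL_GRID, side="left")
    sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(sampled.mean())


def ap_range(dets_by_image: dict, gts_by_image: dict) -> APResult:
    per = {}
    for thr in IOU_THRESHOLDS:
        per[float(thr)] = average_precision(pr_curve(dets_by_image, gts_by_image, float(thr)))
    values = np.array(list(per.values()))
    return APResult(
        ap50=per[0.5], ap75=per[0.75],
        ap_range=float(values.mean()) if not np.all(np.isnan(values)) else float("nan"),
        per_threshold=per,
    )


def evaluate_detections(dets_by_image: dict, annotations: list[AnnotatedImage],
                        subset_or: float = 0.5, subset_min_objects: int = 40) -> dict:
    """Full report: AP metrics on all images plus the dense-occlusion subset."""
    gts_all = {img.image_id: [b.as_array() for b in img.boxes] for img in annotations}
    result = ap_range(dets_by_image, gts_all)
    report = {
        "ap50": result.ap50,
        "ap75": result.ap75,
        "ap_range": result.ap_range,
        "per_threshold": {f"{k:.2f}": v for k, v in result.per_threshold.items()},
        "interpolation": "101-point",
        "n_images": len(annotations),
    }
    dense = dense_subset(annotations, subset_or, subset_min_objects)
    if dense:
        gts_dense = {img.image_id: [b.as_array() for b in img.boxes] for img in dense}
        dets_dense = {k: v for k, v in dets_by_image.items() if k in gts_dense}
        dres = ap_range(dets_dense, gts_dense)
        report["dense_subset"] = {
            "n_images": len(dense),
            "ap50": dres.ap50, "ap75": dres.ap75, "ap_range": dres.ap_range,
        }
    else:
        report["dense_subset"] = {"n_images": 0}
    return report
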