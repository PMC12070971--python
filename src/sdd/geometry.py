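"""Axis-aligned box algebra and the per-image occlusion statistic.

The Overlap Ratio (OR) of a box is the fraction of its area covered by the
union of its intersections with every other annotated box in the image; an
image's OR is the mean over its boxes. The union area is computed exactly by
coordinate-compression sweep, so the statistic is resolution independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box", "AnnotatedImage", "OcclusionReport",
    "iou", "iog", "overlap_ratio", "image_or", "dense_subset",
]


@dataclass(frozen=True)
class Box:
    """Rectangle in continuous corner coordinates (x1, y1) .. (x2, y2)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not all(np.isfinite([self.x1, self.y1, self.x2, self.y2])):
            raise ValueError("box coordinates must be finite")
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(f"degenerate corner order: {self}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    def intersect(self, other: "Box") -> "Box | None":
        x1 = max(self.x1, other.x1)
        y1 = max(self.y1, other.y1)
        x2 = min(self.x2, other.x2)
        y2 = min(self.y2, other.y2)
        if x2 <= x1 or y2 <= y1:
            return None
        return Box(x1, y1, x2, y2)

    def clip(self, width: float, height: float) -> "Box":
        return Box(
            min(max(self.x1, 0.0), width), min(max(self.y1, 0.0), height),
            min(max(self.x2, 0.0), width), min(max(self.y2, 0.0), height),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)


@dataclass
class AnnotatedImage:
    image_id: str
    width: float
    height: float
    boxes: list[Box] = field(default_factory=list)
    class_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.class_ids:
            self.class_ids = [0] * len(self.boxes)
        if len(self.class_ids) != len(self.boxes):
            raise ValueError("boxes and class_ids length mismatch")
        if any(c < 0 for c in self.class_ids):
            raise ValueError("class ids must be nonnegative")
        self.boxes = [b.clip(self.width, self.height) for b in self.boxes]

    @property
    def n_objects(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class OcclusionReport:
    per_box_or: list[float]
    image_or: float
    n_objects: int


def iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 (with a warning) if both boxes have no area."""
    inter = a.intersect(b)
    ia = inter.area if inter is not None else 0.0
    union = a.area + b.area - ia
    if union <= 0.0:
        warnings.warn("IoU of two zero-area boxes defined as 0", stacklevel=2)
        return 0.0
    return ia / union


def iog(p: Box, g: Box) -> float:
    """Intersection over the area of the second (ground-truth) box."""
    if g.area <= 0.0:
        raise ValueError("IoG undefined: ground-truth box has zero area")
    inter = p.intersect(g)
    return (inter.area if inter is not None else 0.0) / g.area


def _union_area(rects: Sequence[Box]) -> float:
    """Exact area of a union of rectangles via coordinate compression."""
    if not rects:
        return 0.0
    xs = np.unique(np.array([[r.x1, r.x2] for r in rects]).ravel())
    ys = np.unique(np.array([[r.y1, r.y2] for r in rects]).ravel())
    covered = np.zeros((len(xs) - 1, len(ys) - 1), dtype=bool)
    for r in rects:
        i1, i2 = np.searchsorted(xs, [r.x1, r.x2])
        j1, j2 = np.searchsorted(ys, [r.y1, r.y2])
        covered[i1:i2, j1:j2] = True
    dx = np.diff(xs)
    dy = np.diff(ys)
    return float((covered * np.outer(dx, dy)).sum())


def overlap_ratio(target: Box, others: Iterable[Box]) -> float:
    """Fraction of `target` covered by the union of intersections with `others`."""
    if target.area <= 0.0:
        raise ValueError("overlap_ratio undefined for a zero-area target box")
    inters = [r for r in (target.intersect(o) for o in others) if r is not None]
    return min(1.0, _union_area(inters) / target.area)


def image_or(img: AnnotatedImage) -> OcclusionReport:
    """Per-box OR against all other boxes and their mean; empty image maps to 0."""
    boxes = [b for b in img.boxes]
    per_box: list[float] = []
    for i, b in enumerate(boxes):
        if b.area <= 0.0:
            per_box.append(0.0)  # fully clipped-away annotation carries no occlusion
            continue
        per_box.append(overlap_ratio(b, boxes[:i] + boxes[i + 1:]))
    mean = float(np.mean(per_box)) if per_box else 0.0
    return OcclusionReport(per_box_or=per_box, image_or=mean, n_objects=len(boxes))


def dense_subset(dataset: Iterable[AnnotatedImage], min_or: float = 0.5,
                 min_objects: int = 40) -> list[AnnotatedImage]:
    """Images whose OR strictly exceeds `min_or` AND object count strictly
    exceeds `min_objects`."""
    kept = []
    for img in dataset:
        rep = image_or(img)
        if rep.image_or > min_or and rep.n_objects > min_objects:
            kept.append(img)
    return kept
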