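"""Reading and writing annotation and detection files.

Supports YOLO txt labels (`class cx cy w h`, normalized, one object per
line), COCO annotation JSON, and COCO-results detection JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

from .geometry import AnnotatedImage, Box

__all__ = [
    "read_yolo_labels", "write_yolo_labels",
    "read_coco_annotations", "write_coco_results", "read_coco_results",
    "load_dataset_dir",
]


def read_yolo_labels(path: str | Path, width: float, height: float,
                     image_id: str | None = None) -> AnnotatedImage:
    boxes, classes = [], []
    path = Path(path)
    if path.exists():
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            cls, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
            boxes.append(Box(
                (cx - w / 2) * width, (cy - h / 2) * height,
                (cx + w / 2) * width, (cy + h / 2) * height,
            ))
            classes.append(cls)
    return AnnotatedImage(image_id or path.stem, width, height, boxes, classes)


def write_yolo_labels(img: AnnotatedImage, path: str | Path) -> None:
    lines = []
    for box, cls in zip(img.boxes, img.class_ids):
        cx = (box.x1 + box.x2) / 2 / img.width
        cy = (box.y1 + box.y2) / 2 / img.height
        w = box.width / img.width
        h = box.height / img.height
        lines.append(f"{cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_coco_annotations(path: str | Path) -> list[AnnotatedImage]:
    data = json.loads(Path(path).read_text())
    images = {im["id"]: AnnotatedImage(str(im["id"]), im["width"], im["height"], [], [])
              for im in data["images"]}
    for ann in data.get("annotations", []):
        x, y, w, h = ann["bbox"]
        img = images[ann["image_id"]]
        img.boxes.append(Box(x, y, x + w, y + h).clip(img.width, img.height))
        img.class_ids.append(int(ann.get("category_id", 0)))
    return list(images.values())


def write_coco_results(detections: dict[str, "DetectionSet"], path: str | Path) -> None:
    rows = []
    for image_id, det in detections.items():
        for box, score, cls in zip(det.boxes, det.scores, det.class_ids):
            rows.append({
                "image_id": image_id,
                "category_id": int(cls),
                "bbox": [float(box[0]), float(box[1]),
                         float(box[2] - box[0]), float(box[3] - box[1])],
                "score": float(score),
            })
    Path(path).write_text(json.dumps(rows, indent=1))


def read_coco_results(path: str | Path) -> dict[str, list[dict]]:
    rows = json.loads(Path(path).read_text())
    per_image: dict[str, list[dict]] = {}
    for r in rows:
        per_image.setdefault(str(r["image_id"]), []).append(r)
    return per_image


def load_dataset_dir(root: str | Path) -> list[AnnotatedImage]:
    """Load a generated dataset directory (manifest.json + YOLO labels)."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    out = []
    for entry in manifest["images"]:
        out.append(read_yolo_labels(root / entry["label"], entry["width"],
                                    entry["height"], image_id=entry["id"]))
    return out
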