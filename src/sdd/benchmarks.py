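"""Published benchmark figures used for reference comparisons.

These are the reported evaluation numbers for YOLO-SDD and competing
detectors on the ChickenFlow, GooseDetect and SheepCounter datasets, plus
the ChickenFlow split sizes. They serve as fixed reference inputs for
consistency arithmetic (improvement margins, reduction percentages); nothing
here is produced by this package's training code.
"""

from __future__ import annotations

__all__ = [
    "CHICKENFLOW_FULL", "CHICKENFLOW_DENSE", "GOOSEDETECT", "SHEEPCOUNTER",
    "CHICKENFLOW_SPLITS",
    "percent_reduction", "metric_difference", "dataset_total_images",
]

# model -> {ap5095, ap50, ap75, flops_g, params_m} on the full ChickenFlow test set
CHICKENFLOW_FULL: dict[str, dict[str, float]] = {
    "yolov5n":      {"ap5095": 75.27, "ap50": 95.86, "ap75": 88.09, "flops_g": 4.1,   "params_m": 1.9},
    "yolov5s":      {"ap5095": 78.64, "ap50": 96.12, "ap75": 90.48, "flops_g": 16.5,  "params_m": 7.2},
    "yolov5m":      {"ap5095": 81.41, "ap50": 96.38, "ap75": 91.29, "flops_g": 49.0,  "params_m": 21.2},
    "yolov7-tiny":  {"ap5095": 74.17, "ap50": 95.54, "ap75": 86.77, "flops_g": 13.7,  "params_m": 6.2},
    "yolov7":       {"ap5095": 79.07, "ap50": 96.48, "ap75": 89.33, "flops_g": 104.7, "params_m": 36.9},
    "yolov8n":      {"ap5095": 79.01, "ap50": 96.28, "ap75": 90.90, "flops_g": 8.7,   "params_m": 3.2},
    "yolov8s":      {"ap5095": 82.14, "ap50": 96.85, "ap75": 92.02, "flops_g": 28.6,  "params_m": 11.2},
    "yolov8m":      {"ap5095": 84.03, "ap50": 96.44, "ap75": 91.95, "flops_g": 78.9,  "params_m": 25.9},
    "yolov9t":      {"ap5095": 77.58, "ap50": 96.20, "ap75": 89.25, "flops_g": 7.7,   "params_m": 2.0},
    "yolov9s":      {"ap5095": 81.04, "ap50": 96.65, "ap75": 91.55, "flops_g": 26.7,  "params_m": 7.2},
    "yolov9m":      {"ap5095": 83.51, "ap50": 96.76, "ap75": 92.61, "flops_g": 76.8,  "params_m": 20.1},
    "yolov10n":     {"ap5095": 79.97, "ap50": 96.66, "ap75": 91.51, "flops_g": 8.4,   "params_m": 2.7},
    "yolov10s":     {"ap5095": 82.64, "ap50": 96.45, "ap75": 92.57, "flops_g": 24.8,  "params_m": 8.6},
    "yolov10m":     {"ap5095": 84.55, "ap50": 96.84, "ap75": 92.73, "flops_g": 64.0,  "params_m": 16.5},
    "mamba-yolo-t": {"ap5095": 79.33, "ap50": 96.07, "ap75": 90.59, "flops_g": 14.3,  "params_m": 6.1},
    "mamba-yolo-b": {"ap5095": 82.43, "ap50": 96.76, "ap75": 92.02, "flops_g": 49.7,  "params_m": 21.8},
    "yolov11n":     {"ap5095": 79.50, "ap50": 96.81, "ap75": 90.96, "flops_g": 6.5,   "params_m": 2.6},
    "yolov11s":     {"ap5095": 82.40, "ap50": 97.01, "ap75": 92.00, "flops_g": 21.5,  "params_m": 9.4},
    "yolov11m":     {"ap5095": 84.01, "ap50": 96.86, "ap75": 92.55, "flops_g": 68.0,  "params_m": 20.1},
    "yolo-sdd-n":   {"ap5095": 81.19, "ap50": 96.90, "ap75": 92.01, "flops_g": 11.4,  "params_m": 2.6},
    "yolo-sdd-s":   {"ap5095": 84.27, "ap50": 97.17, "ap75": 93.24, "flops_g": 28.8,  "params_m": 9.0},
    "yolo-sdd-m":   {"ap5095": 85.65, "ap50": 97.30, "ap75": 93.06, "flops_g": 77.1,  "params_m": 22.0},
}

# dense-occlusion subset of ChickenFlow (image OR > 0.5, more than 40 objects)
CHICKENFLOW_DENSE: dict[str, dict[str, float]] = {
    "yolov5s":      {"ap5095": 71.43, "ap50": 93.06, "ap75": 83.12},
    "yolov8s":      {"ap5095": 72.47, "ap50": 93.17, "ap75": 83.77},
    "yolov9s":      {"ap5095": 72.92, "ap50": 93.28, "ap75": 82.66},
    "yolov10s":     {"ap5095": 73.52, "ap50": 93.53, "ap75": 83.97},
    "mamba-yolo-t": {"ap5095": 70.29, "ap50": 92.70, "ap75": 81.15},
    "yolov11s":     {"ap5095": 72.54, "ap50": 93.26, "ap75": 82.57},
    "yolo-sdd-s":   {"ap5095": 75.60, "ap50": 94.04, "ap75": 85.38},
}

GOOSEDETECT: dict[str, dict[str, float]] = {
    "yolov5s":      {"ap5095": 53.26, "ap50": 90.01, "ap75": 55.97},
    "yolov8s":      {"ap5095": 54.85, "ap50": 90.45, "ap75": 58.01},
    "yolov9s":      {"ap5095": 56.22, "ap50": 91.27, "ap75": 60.36},
    "yolov10s":     {"ap5095": 54.96, "ap50": 90.67, "ap75": 58.81},
    "mamba-yolo-t": {"ap5095": 53.76, "ap50": 89.77, "ap75": 56.59},
    "yolov11s":     {"ap5095": 55.61, "ap50": 90.39, "ap75": 59.75},
    "yolo-sdd-s":   {"ap5095": 56.47, "ap50": 91.71, "ap75": 60.68},
}

SHEEPCOUNTER: dict[str, dict[str, float]] = {
    "yolov5s":      {"ap5095": 58.87, "ap50": 95.62, "ap75": 64.84},
    "yolov8s":      {"ap5095": 60.72, "ap50": 97.38, "ap75": 68.21},
    "yolov9s":      {"ap5095": 61.97, "ap50": 97.19, "ap75": 70.95},
    "yolov10s":     {"ap5095": 61.45, "ap50": 97.57, "ap75": 69.81},
    "mamba-yolo-t": {"ap5095": 59.58, "ap50": 96.93, "ap75": 67.80},
    "yolov11s":     {"ap5095": 60.68, "ap50": 97.26, "ap75": 69.28},
    "yolo-sdd-s":   {"ap5095": 62.35, "ap50": 97.78, "ap75": 71.09},
}

# ChickenFlow image counts per split (7:1:2)
CHICKENFLOW_SPLITS: dict[str, int] = {"train": 3309, "val": 464, "test": 945}


def percent_reduction(table: dict, baseline: str, ours: str, key: str) -> float:
    """100 * (baseline - ours) / baseline, rounded to two decimals."""
    base = table[baseline][key]
    new = table[ours][key]
    return round(100.0 * (base - new) / base, 2)


def metric_difference(table: dict, ours: str, other: str, key: str) -> float:
    """ours minus other, rounded to two decimals."""
    return round(table[ours][key] - table[other][key], 2)


def dataset_total_images(splits: dict[str, int] | None = None) -> int:
    splits = splits or CHICKENFLOW_SPLITS
    return sum(splits.values())
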