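"""Run configuration schema, YAML loading, hashing, and dataset splitting.

Defaults mirror the reference training recipe: AdamW at lr 2e-3 with weight
decay 5e-4, 3 warm-up epochs at momentum 0.9, batch 16, 200 epochs, a 7:1:2
train/val/test split, and occlusion-loss weights alpha=0.4, beta=0.6.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "WEConvConfig", "OpamConfig", "HeadSection", "ModelConfig",
    "LossConfig", "TrainConfig", "DataConfig", "EvalConfig", "RunConfig",
    "load_config", "dump_config", "config_hash", "split_dataset",
]

VARIANT_SCALES: dict[str, tuple[float, float, int]] = {
    # depth multiplier, width multiplier, channel ceiling
    "n": (0.33, 0.25, 1024),
    "s": (0.33, 0.50, 1024),
    "m": (0.67, 0.75, 768),
}


class _Strict(BaseModel):
    model_config = {"extra": "forbid"}


class WEConvConfig(_Strict):
    levels: int = Field(1, ge=1)
    kernel: int = Field(5, ge=1)
    stages: list[int] = [2, 3, 4]  # stage 5 keeps a plain stride conv (parameter parity)


class OpamConfig(_Strict):
    reduction: int = Field(16, ge=1)
    shared_gate: bool = False
    gate_kernel: int = Field(7, ge=1)


class HeadSection(_Strict):
    middle_channel: int = Field(128, ge=16)
    use_dfl: bool = True
    reg_max: int = Field(16, ge=2)


class ModelConfig(_Strict):
    variant: Literal["n", "s", "m"] = "s"
    depth_mult: float | None = Field(None, gt=0)
    width_mult: float | None = Field(None, gt=0)
    input_size: int = 640
    use_weconv: bool = True
    use_opam: bool = True
    use_ls_head: bool = True
    weconv: WEConvConfig = WEConvConfig()
    opam: OpamConfig = OpamConfig()
    head: HeadSection = HeadSection()

    @field_validator("input_size")
    @classmethod
    def _div32(cls, v: int) -> int:
        if v % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        return v

    @property
    def scales(self) -> tuple[float, float, int]:
        d, w, mc = VARIANT_SCALES[self.variant]
        return (self.depth_mult or d, self.width_mult or w, mc)


class LossConfig(_Strict):
    alpha: float = Field(0.4, ge=0)
    beta: float = Field(0.6, ge=0)
    sigma_repgt: float = Field(0.5, ge=0, lt=1)
    sigma_repbox: float = Field(0.5, ge=0, lt=1)
    epsilon: float = Field(1e-7, gt=0)
    cls_weight: float = Field(1.0, ge=0)
    dfl_weight: float = Field(0.25, ge=0)
    use_dfl_loss: bool = True   # off reproduces the bare CIoU + repulsion loss
    repulsion: bool = True      # off drops RepGT/RepBox entirely (ablation row 1)


class TrainConfig(_Strict):
    lr: float = Field(2e-3, gt=0)
    weight_decay: float = Field(5e-4, ge=0)
    warmup_epochs: int = Field(3, ge=0)
    momentum: float = Field(0.9, ge=0, lt=1)
    batch: int = Field(16, ge=1)
    epochs: int = Field(200, ge=1)
    seed: int = 0


class DataConfig(_Strict):
    root: str = "data"
    split: list[float] = [0.7, 0.1, 0.2]

    @field_validator("split")
    @classmethod
    def _sums(cls, v: list[float]) -> list[float]:
        if len(v) != 3 or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("split must be three ratios summing to 1")
        return v


class EvalConfig(_Strict):
    conf_thr: float = Field(1e-3, ge=0, le=1)
    nms_iou: float = Field(0.65, ge=0, le=1)


class RunConfig(_Strict):
    model: ModelConfig = ModelConfig()
    loss: LossConfig = LossConfig()
    train: TrainConfig = TrainConfig()
    data: DataConfig = DataConfig()
    eval: EvalConfig = EvalConfig()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Parse, default, and validate a YAML run config; unknown keys error."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        raw = _deep_merge(raw, overrides)
    return RunConfig.model_validate(raw)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def split_dataset(manifest: list, ratios: list[float] | None = None,
                  seed: int = 0) -> tuple[list, list, list]:
    """Deterministic shuffled partition; val/test get floor shares, the
    remainder goes to training."""
    ratios = ratios or [0.7, 0.1, 0.2]
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be three values summing to 1")
    items = list(manifest)
    order = np.random.default_rng(seed).permutation(len(items))
    n = len(items)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    shuffled = [items[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])
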