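"""Lightweight shared detection head.

Each pyramid level is first reduced by a level-specific 1x1 convolution to a
common middle channel width; the two 3x3 group-normalized blocks and the
classification/regression prediction convolutions are then *shared* across
all levels (single parameter storage), with a per-level learnable scalar on
the regression output to absorb scale differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .nn import Conv2d, ConvGN, GroupNorm, Module, Parameter, Sequential

__all__ = ["HeadConfig", "GNConv", "LSHead", "DecoupledHead",
           "count_head_params", "count_decoupled_head_params"]

GN_GROUPS = 16


@dataclass
class HeadConfig:
    middle_channel: int = 128
    num_levels: int = 3
    reg_max: int = 16
    use_dfl: bool = True
    num_classes: int = 1

    @property
    def reg_out(self) -> int:
        return 4 * self.reg_max if self.use_dfl else 4


class GNConv(Module):
    """3x3 convolution -> GroupNorm(16 groups) -> SiLU; shape preserving."""

    def __init__(self, rng, channels: int):
        if channels % GN_GROUPS != 0:
            raise ValueError(f"GNConv needs channels divisible by {GN_GROUPS}, got {channels}")
        self.conv = Conv2d(rng, channels, channels, kernel=3, bias=False)
        self.norm = GroupNorm(GN_GROUPS, channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).silu()


class LSHead(Module):
    def __init__(self, rng, in_channels: list[int], cfg: HeadConfig | None = None):
        cfg = cfg or HeadConfig()
        if len(in_channels) != cfg.num_levels:
            raise ValueError("one input channel count per level required")
        self.cfg = cfg
        mid = cfg.middle_channel
        self.reduce = [ConvGN(rng, c, mid, kernel=1) for c in in_channels]
        self.shared1 = GNConv(rng, mid)
        self.shared2 = GNConv(rng, mid)
        self.cls_pred = Conv2d(rng, mid, cfg.num_classes, kernel=1, bias=True)
        self.reg_pred = Conv2d(rng, mid, cfg.reg_out, kernel=1, bias=True)
        self.scales = [Parameter(np.ones(1)) for _ in range(cfg.num_levels)]

    def forward(self, *levels: Tensor) -> list[tuple[Tensor, Tensor]]:
        if len(levels) != self.cfg.num_levels:
            raise ValueError(f"expected {self.cfg.num_levels} levels, got {len(levels)}")
        outputs = []
        for i, x in enumerate(levels):
            f = self.shared2(self.shared1(self.reduce[i](x)))
            cls = self.cls_pred(f)
            reg = self.reg_pred(f) * self.scales[i].reshape(1, 1, 1, 1)
            outputs.append((cls, reg))
        return outputs


def count_head_params(cfg: HeadConfig, in_channels: list[int]) -> int:
    """Closed-form learned-parameter count of :class:`LSHead`."""
    mid = cfg.middle_channel
    total = sum(c * mid + 2 * mid for c in in_channels)          # 1x1 reductions + GN affine
    total += 2 * (mid * mid * 9 + 2 * mid)                       # two shared GNConv blocks
    total += mid * cfg.num_classes + cfg.num_classes             # shared cls prediction
    total += mid * cfg.reg_out + cfg.reg_out                     # shared reg prediction
    total += cfg.num_levels                                      # per-level reg scales
    return total


def _decoupled_widths(cfg: HeadConfig, in_channels: list[int]) -> tuple[int, int]:
    """Hidden widths of the decoupled baseline head: the regression stem is
    narrowed, the classification stem keeps the first level's width."""
    hid_reg = max(16, in_channels[0] // 4, 4 * cfg.reg_max)
    hid_cls = max(in_channels[0], min(cfg.num_classes, 100))
    return hid_reg, hid_cls


class DecoupledHead(Module):
    """Baseline-style decoupled head: independent cls/reg stems per level."""

    def __init__(self, rng, in_channels: list[int], cfg: HeadConfig | None = None):
        cfg = cfg or HeadConfig()
        self.cfg = cfg
        hr, hc = _decoupled_widths(cfg, in_channels)
        self.cls_stems = []
        self.reg_stems = []
        self.cls_preds = []
        self.reg_preds = []
        for c in in_channels:
            self.cls_stems.append(Sequential(ConvGN(rng, c, hc, kernel=3), ConvGN(rng, hc, hc, kernel=3)))
            self.reg_stems.append(Sequential(ConvGN(rng, c, hr, kernel=3), ConvGN(rng, hr, hr, kernel=3)))
            self.cls_preds.append(Conv2d(rng, hc, cfg.num_classes, kernel=1, bias=True))
            self.reg_preds.append(Conv2d(rng, hr, cfg.reg_out, kernel=1, bias=True))

    def forward(self, *levels: Tensor) -> list[tuple[Tensor, Tensor]]:
        outputs = []
        for i, x in enumerate(levels):
            c = self.cls_stems[i](x)
            r = self.reg_stems[i](x)
            outputs.append((self.cls_preds[i](c), self.reg_preds[i](r)))
        return outputs


def count_decoupled_head_params(cfg: HeadConfig, in_channels: list[int]) -> int:
    hr, hc = _decoupled_widths(cfg, in_channels)
    total = 0
    for c in in_channels:
        total += (c * hc * 9 + 2 * hc) + (hc * hc * 9 + 2 * hc)  # cls stem
        total += (c * hr * 9 + 2 * hr) + (hr * hr * 9 + 2 * hr)  # reg stem
        total += hc * cfg.num_classes + cfg.num_classes
        total += hr * cfg.reg_out + cfg.reg_out
    return total
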