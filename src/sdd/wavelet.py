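"""Haar wavelet analysis/synthesis and wavelet-enhanced convolution blocks.

The transform uses the orthonormal Haar filters (coefficients +-1/2), so one
analysis/synthesis round trip is exact and the subband energies sum to the
input energy. `WTConv` applies learned depthwise kernels to every subband of
a multi-level decomposition plus a spatial-domain depthwise path; `WEConv`
wraps it into a stride-2 downsampling block (pointwise reduction -> wavelet
enrichment -> additive fusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, cat
from .nn import Conv2d, Module, Parameter

__all__ = ["WaveletBands", "haar_dwt2", "haar_iwt2", "WTConv", "WEConv"]


@dataclass
class WaveletBands:
    ll: Tensor
    lh: Tensor
    hl: Tensor
    hh: Tensor

    def __post_init__(self):
        shapes = {t.shape for t in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent band shapes: {shapes}")


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _pad_even(x: Tensor) -> tuple[Tensor, int, int]:
    """Replicate-pad the bottom/right edge so both spatial sizes are even."""
    h, w = x.shape[-2], x.shape[-1]
    ph, pw = h % 2, w % 2
    if ph:
        x = cat([x, x[..., -1:, :]], axis=-2)
    if pw:
        x = cat([x, x[..., :, -1:]], axis=-1)
    return x, ph, pw


def haar_dwt2(x) -> WaveletBands:
    """Single-level 2-D Haar analysis along the two trailing axes.

    Odd extents are replicate-padded to even before analysis.
    """
    x = _lift(x)
    x, _, _ = _pad_even(x)
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5   # horizontal detail
    hl = (a + b - c - d) * 0.5   # vertical detail
    hh = (a - b - c + d) * 0.5   # diagonal detail
    return WaveletBands(ll, lh, hl, hh)


def haar_iwt2(bands: WaveletBands) -> Tensor:
    """Exact inverse of :func:`haar_dwt2` (up to any odd-size padding)."""
    ll, lh, hl, hh = bands.ll, bands.lh, bands.hl, bands.hh
    a = (ll + lh + hl + hh) * 0.5
    b = (ll - lh + hl - hh) * 0.5
    c = (ll + lh - hl - hh) * 0.5
    d = (ll - lh - hl + hh) * 0.5
    lead = a.shape[:-2]
    h, w = a.shape[-2], a.shape[-1]
    # interleave columns then rows
    top = cat([a.reshape(*lead, h, w, 1), b.reshape(*lead, h, w, 1)], axis=-1).reshape(*lead, h, 2 * w)
    bot = cat([c.reshape(*lead, h, w, 1), d.reshape(*lead, h, w, 1)], axis=-1).reshape(*lead, h, 2 * w)
    out = cat([top.reshape(*lead, h, 1, 2 * w), bot.reshape(*lead, h, 1, 2 * w)], axis=-2)
    return out.reshape(*lead, 2 * h, 2 * w)


class WTConv(Module):
    """Depthwise convolution carried out in the Haar wavelet domain.

    The low-frequency band is decomposed `levels` times; learned depthwise
    kernels act on the three detail bands of every level and on the deepest
    approximation band, the result is synthesized back, and a depthwise
    spatial-domain path on the input is added. Linear in its input.
    """

    def __init__(self, rng, channels: int, levels: int = 1, kernel: int = 5):
        if levels < 1:
            raise ValueError("levels must be >= 1")
        self.channels, self.levels, self.kernel = channels, levels, kernel
        mk = lambda: Conv2d(rng, channels, channels, kernel, groups=channels, bias=False)
        self.detail_convs = [[mk(), mk(), mk()] for _ in range(levels)]
        self.ll_conv = mk()
        self.spatial = mk()

    def init_identity(self) -> None:
        """Delta band kernels and zero spatial path: forward becomes identity."""
        k = self.kernel
        delta = np.zeros((self.channels, 1, k, k), dtype=np.float32)
        delta[:, 0, k // 2, k // 2] = 1.0
        for lvl in self.detail_convs:
            for conv in lvl:
                conv.weight.data = delta.copy()
        self.ll_conv.weight.data = delta.copy()
        self.spatial.weight.data = np.zeros_like(delta)

    def forward(self, x) -> Tensor:
        x = _lift(x)
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)
        if min(x.shape[-2], x.shape[-1]) < 2 ** self.levels:
            raise ValueError(
                f"spatial size {x.shape[-2:]} too small for {self.levels} wavelet levels")
        out = self.spatial(x) + self._wt(x, 0)
        return out.reshape(*out.shape[1:]) if squeeze else out

    def _wt(self, x: Tensor, level: int) -> Tensor:
        h, w = x.shape[-2], x.shape[-1]
        bands = haar_dwt2(x)
        clh, chl, chh = self.detail_convs[level]
        lh, hl, hh = clh(bands.lh), chl(bands.hl), chh(bands.hh)
        if level + 1 < self.levels:
            ll = self._wt(bands.ll, level + 1)
        else:
            ll = self.ll_conv(bands.ll)
        y = haar_iwt2(WaveletBands(ll, lh, hl, hh))
        if y.shape[-2] != h or y.shape[-1] != w:  # crop odd-size padding
            y = y[..., :h, :w]
        return y


class WEConv(Module):
    """Wavelet-enhanced downsampling: stride-2 pointwise reduction, wavelet
    enrichment of the reduced map, additive fusion, SiLU."""

    def __init__(self, rng, c_in: int, c_out: int, levels: int = 1, kernel: int = 5):
        self.pw = Conv2d(rng, c_in, c_out, kernel=1, stride=2, bias=False)
        self.wt = WTConv(rng, c_out, levels=levels, kernel=kernel)

    def forward(self, x) -> Tensor:
        x = _lift(x)
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)
        xd = self.pw(x)
        out = (xd + self.wt(xd)).silu()
        return out.reshape(*out.shape[1:]) if squeeze else out
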