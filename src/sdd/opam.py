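"""Occlusion-perceptual attention fusion of low-level and high-level features.

The low-level stream (stride 4, detail-rich) is brought to the high-level
stream's grid, both are self-enhanced (spatial gate on the low stream,
squeeze-excitation on the high stream), a sigmoid pixel gate is computed from
the pair, and the output is the per-position convex combination

    F_out = F_low * F_pixel + Conv1x1(F_high) * (1 - F_pixel).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, cat
from .nn import Conv2d, ConvGN, Module

__all__ = ["PositionAttention", "ChannelAttention", "PixelAttention", "OPAM"]


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _batched(x: Tensor) -> tuple[Tensor, bool]:
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    return x, False


class PositionAttention(Module):
    """Spatial gate from channel-pooled descriptors (mean and max over C),
    passed through a 7x7 reflect-padded convolution and a sigmoid."""

    def __init__(self, rng, kernel: int = 7):
        self.conv = Conv2d(rng, 2, 1, kernel=kernel, bias=True, pad_mode="reflect")

    def forward(self, x) -> Tensor:
        x, squeeze = _batched(_lift(x))
        mean_c = x.mean(axis=1, keepdims=True)
        # max over channels as a constant-index gather keeps the graph cheap
        arg = x.data.argmax(axis=1, keepdims=True)
        n, _, h, w = x.shape
        ni = np.arange(n)[:, None, None, None]
        hi = np.arange(h)[None, None, :, None]
        wi = np.arange(w)[None, None, None, :]
        max_c = x[ni, arg, hi, wi]
        gate = self.conv(cat([mean_c, max_c], axis=1)).sigmoid()
        out = x * gate
        return out.reshape(*out.shape[1:]) if squeeze else out


class ChannelAttention(Module):
    """Squeeze-excitation: global average pool -> bottleneck -> sigmoid gate,
    constant across spatial positions."""

    def __init__(self, rng, channels: int, reduction: int = 16):
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(rng, channels, hidden, kernel=1, bias=True)
        self.fc2 = Conv2d(rng, hidden, channels, kernel=1, bias=True)

    def forward(self, x) -> Tensor:
        x, squeeze = _batched(_lift(x))
        pooled = x.mean(axis=(2, 3), keepdims=True)
        gate = self.fc2(self.fc1(pooled).silu()).sigmoid()
        out = x * gate
        return out.reshape(*out.shape[1:]) if squeeze else out

    def gate(self, x) -> Tensor:
        x, _ = _batched(_lift(x))
        pooled = x.mean(axis=(2, 3), keepdims=True)
        return self.fc2(self.fc1(pooled).silu()).sigmoid()


class PixelAttention(Module):
    """Sigmoid pixel gate from the concatenated enhanced streams; per-channel
    by default, scalar per position when `shared_gate`."""

    def __init__(self, rng, c_a: int, c_b: int, c_out: int, shared_gate: bool = False):
        gate_c = 1 if shared_gate else c_out
        self.conv1 = Conv2d(rng, c_a + c_b, c_out, kernel=1, bias=True)
        self.conv2 = Conv2d(rng, c_out, gate_c, kernel=1, bias=True)

    def forward(self, a, b) -> Tensor:
        a, squeeze = _batched(_lift(a))
        b, _ = _batched(_lift(b))
        if a.shape[-2:] != b.shape[-2:]:
            raise ValueError(f"spatial mismatch: {a.shape[-2:]} vs {b.shape[-2:]}")
        gate = self.conv2(self.conv1(cat([a, b], axis=1)).silu()).sigmoid()
        return gate.reshape(*gate.shape[1:]) if squeeze else gate


class OPAM(Module):
    """Full fusion block: resample low stream to the high stream's stride,
    attend, gate, and blend."""

    def __init__(self, rng, c_low: int, c_high: int, c_out: int,
                 reduction: int = 16, shared_gate: bool = False, gate_kernel: int = 7):
        self.down = ConvGN(rng, c_low, c_out, kernel=3, stride=2)
        self.pa = PositionAttention(rng, kernel=gate_kernel)
        self.ca = ChannelAttention(rng, c_high, reduction=reduction)
        self.proj = Conv2d(rng, c_high, c_out, kernel=1, bias=True)  # bare linear
        self.px = PixelAttention(rng, c_out, c_high, c_out, shared_gate=shared_gate)
        self._forced_gate: float | None = None

    def force_gate(self, value: float | None) -> None:
        """Pin the pixel gate to a constant (used by the limit tests)."""
        self._forced_gate = value

    def forward(self, f_low, f_high) -> Tensor:
        f_low, squeeze = _batched(_lift(f_low))
        f_high, _ = _batched(_lift(f_high))
        low = self.down(f_low)
        if self._forced_gate is None:
            a = low + self.pa(low)
            b = f_high + self.ca(f_high)
            gate = self.px(a, b)
        else:
            gate = Tensor(np.full((1, 1, 1, 1), self._forced_gate, dtype=np.float32))
        high = self.proj(f_high)
        out = low * gate + high * (1.0 - gate)
        return out.reshape(*out.shape[1:]) if squeeze else out
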