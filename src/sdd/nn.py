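"""Lightweight neural-network module system on top of :mod:`sdd.autograd`.

Deliberately small: Conv2d, GroupNorm, SiLU-fused conv blocks, Sequential,
and AdamW. Initialization is driven by an explicit numpy Generator so model
construction is reproducible from a single seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d, pad2d

__all__ = ["Module", "Parameter", "Conv2d", "GroupNorm", "ConvGN", "Sequential", "AdamW"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for p in self._walk_params():
            if id(p) not in seen:  # shared weights counted once
                seen.add(id(p))
                yield p

    def _walk_params(self) -> Iterator[Parameter]:
        def walk(v):
            if isinstance(v, Parameter):
                yield v
            elif isinstance(v, Module):
                yield from v._walk_params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)

        for v in vars(self).values():
            yield from walk(v)

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        out = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict) -> None:
        for k, p in self._named_params():
            out[prefix + k] = p.data

    def _named_params(self) -> Iterator[tuple[str, Parameter]]:
        def walk(name, v):
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                for sub, p in v._named_params():
                    yield f"{name}.{sub}", p
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    yield from walk(f"{name}.{i}", item)

        for k, v in vars(self).items():
            yield from walk(k, v)

    def load_state_dict(self, state: dict) -> None:
        own = {}
        self._collect_params("", own)
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)[:5]} ...")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float32)

    def _collect_params(self, prefix: str, out: dict) -> None:
        for k, p in self._named_params():
            out[prefix + k] = p

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = math.sqrt(2.0 / fan_in) if fan_in > 0 else 0.0
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, kernel=1, stride=1, padding=None,
                 groups=1, bias=True, pad_mode="constant"):
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        self.pad_mode = pad_mode
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = (c_in // groups) * kernel * kernel
        self.weight = Parameter(kaiming(rng, (c_out, c_in // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups, pad_mode=self.pad_mode)


class GroupNorm(Module):
    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        if channels % num_groups != 0:
            raise ValueError(f"channels={channels} not divisible by groups={num_groups}")
        self.g, self.c, self.eps = num_groups, channels, eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        xg = x.reshape(n, self.g, c // self.g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        xn = xn.reshape(n, c, h, w)
        return xn * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


def auto_groups(channels: int, preferred: int = 16) -> int:
    g = min(preferred, channels)
    while channels % g != 0:
        g -= 1
    return g


class ConvGN(Module):
    """Conv -> GroupNorm -> SiLU, the basic block of backbone and neck."""

    def __init__(self, rng, c_in, c_out, kernel=3, stride=1, groups=1, act=True):
        self.conv = Conv2d(rng, c_in, c_out, kernel, stride, groups=groups, bias=False)
        self.norm = GroupNorm(auto_groups(c_out), c_out)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        return y.silu() if self.act else y


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class AdamW:
    def __init__(self, params, lr=2e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=5e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * self.wd * p.data  # decoupled decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
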