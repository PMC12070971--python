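"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set needed by the detection model: broadcasted
elementwise arithmetic, a handful of transcendentals, reductions, shape
surgery, 2-D (grouped) convolution, max pooling, nearest upsampling, and
padding. Gradients accumulate, so weight sharing across call sites (e.g. a
detection head applied to several pyramid levels) works out of the box.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "cat", "where", "conv2d", "maxpool2d", "upsample2x", "pad2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # ------------------------------------------------------------- autograd
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        needs = any(p.requires_grad for p in parents)
        out.requires_grad = needs
        out._parents = tuple(p for p in parents if p.requires_grad) if needs else ()
        out._backward = backward if needs else None
        return out

    def __add__(self, other):
        other = Tensor._lift(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        data = -self.data

        def backward(g):
            self._accumulate(-g)

        return Tensor._make(data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), backward)

    # --------------------------------------------------------- transcendental
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(data, (self,), backward)

    def sqrt(self):
        data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / np.maximum(data, np.finfo(data.dtype).tiny))

        return Tensor._make(data, (self,), backward)

    def arctan(self):
        data = np.arctan(self.data)

        def backward(g):
            self._accumulate(g / (1.0 + self.data ** 2))

        return Tensor._make(data, (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        data = self.data * s

        def backward(g):
            self._accumulate(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(data, (self,), backward)

    def softplus(self):
        # log(1 + e^x), numerically stable
        data = np.logaddexp(0.0, self.data).astype(self.data.dtype)

        def backward(g):
            self._accumulate(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(data, (self,), backward)

    def maximum(self, other):
        other = Tensor._lift(other)
        data = np.maximum(self.data, other.data)

        def backward(g):
            mask = self.data >= other.data  # subgradient: ties go to self
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~mask, other.shape))

        return Tensor._make(data, (self, other), backward)

    def minimum(self, other):
        other = Tensor._lift(other)
        data = np.minimum(self.data, other.data)

        def backward(g):
            mask = self.data <= other.data
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~mask, other.shape))

        return Tensor._make(data, (self, other), backward)

    def clamp_min(self, value: float):
        return self.maximum(Tensor(np.asarray(value, dtype=self.data.dtype)))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(np.asarray(data), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)  # constant shift, exact grad
        e = (self - m).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # --------------------------------------------------------- shape surgery
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(data, (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(data, (self,), backward)


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def where(mask: np.ndarray, a, b) -> Tensor:
    """Elementwise select with a *constant* boolean mask."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    mask = np.asarray(mask, dtype=bool)
    data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~mask, b.shape))

    return Tensor._make(data, (a, b), backward)


def pad2d(x: Tensor, pad: int, mode: str = "constant") -> Tensor:
    """Pad the two trailing (spatial) axes."""
    if pad == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    data = np.pad(x.data, widths, mode=mode)

    def backward(g):
        if mode == "constant":
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            x._accumulate(g[sl])
        else:  # reflect: fold padded gradient back onto source positions
            h, w = x.shape[-2], x.shape[-1]
            idx_h = np.pad(np.arange(h), (pad, pad), mode=mode)
            idx_w = np.pad(np.arange(w), (pad, pad), mode=mode)
            lead = x.data.shape[:-2]
            g2 = g.reshape(-1, g.shape[-2], g.shape[-1])
            core = np.zeros((g2.shape[0], h, w), dtype=g.dtype)
            bi = np.arange(g2.shape[0])[:, None, None]
            np.add.at(core, (bi, idx_h[None, :, None], idx_w[None, None, :]), g2)
            x._accumulate(core.reshape(*lead, h, w))

    return Tensor._make(data, (x,), backward)


_conv_flops_hooks: list = []


class flop_counter:
    """Context manager accumulating 2*MAC counts of conv/pool ops run inside."""

    def __init__(self):
        self.total = 0

    def add(self, n: int):
        self.total += int(n)

    def __enter__(self):
        _conv_flops_hooks.append(self)
        return self

    def __exit__(self, *exc):
        _conv_flops_hooks.remove(self)
        return False


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1, pad_mode: str = "constant") -> Tensor:
    """Grouped cross-correlation. x: (N,C,H,W); w: (Cout, Cin/groups, kh, kw)."""
    xp = pad2d(x, padding, mode=pad_mode) if padding else x
    n, cin, h, wd = xp.shape
    cout, cin_g, kh, kw = w.shape
    assert cin == cin_g * groups, f"channel mismatch: {cin} vs {cin_g}*{groups}"
    assert cout % groups == 0
    cout_g = cout // groups
    s = stride
    ho = (h - kh) // s + 1
    wo = (wd - kw) // s + 1

    v = sliding_window_view(xp.data, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    v = v.reshape(n, groups, cin_g, ho, wo, kh, kw)
    w_ = w.data.reshape(groups, cout_g, cin_g, kh, kw)
    out = np.einsum("ngchwkl,gdckl->ngdhw", v, w_, optimize=True)
    out = np.ascontiguousarray(out.reshape(n, cout, ho, wo))
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    for hook in _conv_flops_hooks:
        hook.add(2 * n * groups * cout_g * cin_g * kh * kw * ho * wo)

    def backward(g):
        g_ = g.reshape(n, groups, cout_g, ho, wo)
        if w.requires_grad:
            gw = np.einsum("ngchwkl,ngdhw->gdckl", v, g_, optimize=True)
            w._accumulate(gw.reshape(cout, cin_g, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            gcol = np.einsum("gdckl,ngdhw->ngchwkl", w_, g_, optimize=True)
            gxp = np.zeros((n, cin, h, wd), dtype=g.dtype)
            gcol = gcol.reshape(n, cin, ho, wo, kh, kw)
            for a in range(kh):
                for c in range(kw):
                    gxp[:, :, a:a + s * ho:s, c:c + s * wo:s] += gcol[..., a, c]
            xp._accumulate(gxp)

    parents = (xp, w) if b is None else (xp, w, b)
    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    if padding:
        widths = [(0, 0)] * (x.ndim - 2) + [(padding, padding), (padding, padding)]
        data_p = np.pad(x.data, widths, mode="constant", constant_values=-np.inf)
    else:
        data_p = x.data
    n, c, h, wd = data_p.shape
    s = stride
    ho = (h - kernel) // s + 1
    wo = (wd - kernel) // s + 1
    v = sliding_window_view(data_p, (kernel, kernel), axis=(2, 3))[:, :, ::s, ::s]
    vf = v.reshape(n, c, ho, wo, kernel * kernel)
    arg = vf.argmax(axis=-1)
    out = np.take_along_axis(vf, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros((n, c, h, wd), dtype=g.dtype)
        ky, kx = np.unravel_index(arg, (kernel, kernel))
        iy = (np.arange(ho) * s)[None, None, :, None] + ky
        ix = (np.arange(wo) * s)[None, None, None, :] + kx
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (ni, ci, iy, ix), g)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)
    n, c, h, w = x.shape

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(data, (x,), backward)
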