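"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients into ``.grad``.  Only the
operations needed by the convolutional self-attention networks in this
package are provided (elementwise arithmetic, matmul with broadcasting,
conv2d via im2col, 2x2 max pooling, softmax, layer norm, GELU/ReLU,
reductions and shape ops).

Gradients are accumulated on every tensor in the graph, so gradients with
respect to intermediate activations (needed by Grad-CAM) are available after
``backward`` without extra bookkeeping.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "cat", "softmax", "layer_norm"]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_DTYPE, copy=False)
    return np.asarray(x, dtype=_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basics ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    # -- autodiff driver ------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor.

        ``grad`` defaults to ones (a scalar loss needs no seed).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only inside the range."""
        out_data = np.clip(self.data, lo, hi)
        mask = ((self.data > lo) & (self.data < hi)).astype(_DTYPE)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0)
        mask = (self.data > 0).astype(_DTYPE)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def gelu(self) -> "Tensor":
        x = self.data.astype(np.float64)
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = (x * phi).astype(_DTYPE)
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        deriv = (phi + x * pdf).astype(_DTYPE)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * deriv)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def broadcast_to(self, shape: tuple[int, ...]) -> "Tensor":
        out_data = np.broadcast_to(self.data, shape).copy()
        orig = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, orig))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- conv / pool ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution (cross-correlation), NCHW layout, via im2col."""
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        o, cw, kh, kw = w.shape
        if cw != c:
            raise ValueError(f"channel mismatch: input {c}, weight {cw}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (wd + 2 * padding - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]            # (n, c, ho, wo, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
        cols = cols.reshape(n, c * kh * kw, ho * wo)   # (n, ckk, howo)
        wmat = w.reshape(o, c * kh * kw)
        out = np.matmul(wmat, cols).reshape(n, o, ho, wo)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def bwd(g):
            gmat = g.reshape(n, o, ho * wo)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                gw = np.einsum("nop,ncp->oc", gmat, cols, optimize=True)
                weight._accumulate(gw.reshape(w.shape))
            if self.requires_grad:
                gcols = np.matmul(wmat.T[None], gmat)  # (n, ckk, howo)
                gcols = gcols.reshape(n, c, kh, kw, ho, wo)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + ho * stride:stride,
                            j:j + wo * stride:stride] += gcols[:, :, i, j]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(gxp)

        return Tensor(out, _parents=parents, _backward=bwd)

    def maxpool2x2(self) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2x2 requires even spatial dimensions")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            if not self.requires_grad:
                return
            g4 = np.zeros_like(win)
            np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
            gx = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accumulate(gx.reshape(n, c, h, w))

        return Tensor(out, _parents=(self,), _backward=bwd)


def cat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    return Tensor(y, _parents=(x,), _backward=bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data
    d = x.shape[-1]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx - gx.mean(axis=-1, keepdims=True)
            t2 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (t1 - t2))

    return Tensor(out, _parents=(x, gamma, beta), _backward=bwd)
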