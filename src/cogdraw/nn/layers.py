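"""Neural-network building blocks on top of the autodiff core.

Modules follow a tiny torch-like convention: each exposes ``parameters()``
returning its trainable :class:`~cogdraw.nn.autodiff.Tensor` objects and is
callable on tensors.  Weight initialization is He/Glorot style and fully
determined by the ``numpy.random.Generator`` passed to the constructor.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, cat, layer_norm, softmax

__all__ = [
    "Module", "Conv2d", "Linear", "LayerNorm",
    "SelfAttentionLayer", "TransformerEncoder", "Adam",
]


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Tensor(rng.normal(0.0, scale, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class SelfAttentionLayer(Module):
    """Single-head self-attention encoder block (post-LN).

    Attention output is ``softmax(Q K^T / sqrt(D)) V`` added back to the
    residual stream (no output projection), followed by a two-layer
    feed-forward sublayer; each sublayer is wrapped by a residual connection
    and layer normalization.  The row-stochastic attention-weight matrix of
    the most recent forward pass is kept in ``last_attention`` for rollout.
    """

    def __init__(self, dim: int, ffn_dim: int, rng: np.random.Generator):
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.ln1 = LayerNorm(dim)
        self.ffn1 = Linear(dim, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, dim, rng)
        self.ln2 = LayerNorm(dim)
        self.dim = dim
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.dim))
        w_att = softmax(logits, axis=-1)
        self.last_attention = w_att.data.copy()
        x = self.ln1(x + (w_att @ v))
        x = self.ln2(x + self.ffn2(self.ffn1(x).gelu()))
        return x


class TransformerEncoder(Module):
    """Stack of self-attention layers over a CLS-prefixed token matrix."""

    def __init__(self, n_layers: int, dim: int, ffn_dim: int,
                 rng: np.random.Generator):
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.layers = [SelfAttentionLayer(dim, ffn_dim, rng)
                       for _ in range(n_layers)]

    def __call__(self, tokens: Tensor) -> tuple[Tensor, list[np.ndarray]]:
        trace: list[np.ndarray] = []
        for layer in self.layers:
            tokens = layer(tokens)
            trace.append(layer.last_attention)
        return tokens, trace


class Adam:
    """Adam optimizer implementing the standard bias-corrected update."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.99, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
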