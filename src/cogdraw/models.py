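"""Multi-input convolutional self-attention networks.

Architecture (one pathway per drawing task):

    image (3, S, S)
      -> CNN backbone                        last feature map X (C, H, L)
      -> 1x1 projection to hidden dim D      tokens (HL, D), row-major
      -> prepend learned CLS vector          token matrix (HL+1, D)
      -> stack of single-head self-attention encoder layers
      -> CLS output vector (D,)

The per-task CLS vectors are concatenated and mapped by a two-node affine
layer with softmax to (p_healthy, p_MCI).  The pooling baseline replaces
projection + attention with global average pooling of the feature map.

Token convention: token 0 is CLS; token ``1 + r*L + c`` is feature-grid
pixel (r, c).  Heat-map reshaping in :mod:`cogdraw.explain` inverts exactly
this mapping.
"""

from __future__ import annotations

import numpy as np

from .nn import (Linear, Module, Tensor, TransformerEncoder, build_backbone,
                 cat, softmax)

DEFAULT_HIDDEN_DIM = 128
DEFAULT_FFN_DIM = 512
DEFAULT_N_LAYERS = 2

__all__ = [
    "ConvAttNet", "PoolingNet", "backbone_forward", "tokenize",
    "self_attention", "encoder_forward", "aggregate_and_classify",
    "pooling_baseline_forward",
]


class _AttPathway(Module):
    def __init__(self, backbone: str, n_layers: int, hidden_dim: int,
                 ffn_dim: int, rng: np.random.Generator):
        self.backbone = build_backbone(backbone, rng)
        self.proj = Linear(self.backbone.out_channels, hidden_dim, rng)
        self.cls = Tensor(rng.normal(0.0, 0.02, hidden_dim), requires_grad=True)
        self.encoder = TransformerEncoder(n_layers, hidden_dim, ffn_dim, rng)
        self.hidden_dim = hidden_dim


class ConvAttNet(Module):
    """Multi-input (or single-input) Conv-Att network."""

    def __init__(self, tasks: tuple[str, ...], backbone: str = "vgg16",
                 n_layers: int = DEFAULT_N_LAYERS,
                 hidden_dim: int = DEFAULT_HIDDEN_DIM,
                 ffn_dim: int = DEFAULT_FFN_DIM,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.tasks = tuple(tasks)
        self.pathways = [_AttPathway(backbone, n_layers, hidden_dim, ffn_dim, rng)
                         for _ in self.tasks]
        self.head = Linear(len(self.tasks) * hidden_dim, 2, rng)
        self.hidden_dim = hidden_dim
        self.grid_shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> tuple[Tensor, dict[str, list[np.ndarray]]]:
        """Forward a batch ``x`` of shape (N, n_tasks, 3, S, S).

        Returns class probabilities (N, 2) and the per-task attention trace
        (one (N, HL+1, HL+1) row-stochastic matrix per encoder layer).
        """
        if x.ndim != 5 or x.shape[1] != len(self.tasks):
            raise ValueError(
                f"expected (N, {len(self.tasks)}, 3, S, S) input, got {x.shape}")
        cls_vecs, traces = [], {}
        for t, task in enumerate(self.tasks):
            pw = self.pathways[t]
            feat = pw.backbone(Tensor(x[:, t]))
            n, c, h, w = feat.shape
            self.grid_shape = (h, w)
            tokens = feat.reshape(n, c, h * w).transpose(0, 2, 1)
            tokens = pw.proj(tokens)                        # (N, HL, D)
            cls_tok = pw.cls.reshape(1, 1, self.hidden_dim)
            cls_tok = cls_tok.broadcast_to((n, 1, self.hidden_dim))
            tok = cat([cls_tok, tokens], axis=1)            # CLS is row 0
            tok, trace = pw.encoder(tok)
            traces[task] = trace
            cls_vecs.append(tok[:, 0, :])
        logits = self.head(cat(cls_vecs, axis=1))
        return softmax(logits, axis=-1), traces


class PoolingNet(Module):
    """Global-average-pooling baseline (single- or multi-input)."""

    def __init__(self, tasks: tuple[str, ...], backbone: str = "vgg16",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.tasks = tuple(tasks)
        self.backbones = [build_backbone(backbone, rng) for _ in self.tasks]
        c = self.backbones[0].out_channels
        self.head = Linear(len(self.tasks) * c, 2, rng)
        self.last_features: list[Tensor] = []
        self.last_logits: Tensor | None = None
        self.grid_shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> tuple[Tensor, dict]:
        if x.ndim != 5 or x.shape[1] != len(self.tasks):
            raise ValueError(
                f"expected (N, {len(self.tasks)}, 3, S, S) input, got {x.shape}")
        pooled = []
        self.last_features = []
        for t in range(len(self.tasks)):
            feat = self.backbones[t](Tensor(x[:, t]))       # (N, C, H, L)
            self.last_features.append(feat)
            self.grid_shape = feat.shape[2:]
            pooled.append(feat.mean(axis=(2, 3)))           # (N, C)
        self.last_logits = self.head(cat(pooled, axis=1))
        return softmax(self.last_logits, axis=-1), {}


# ---------------------------------------------------------------------------
# functional surface (thin wrappers used directly in tests and docs)
# ---------------------------------------------------------------------------

def backbone_forward(image: np.ndarray, backbone: str = "vgg16",
                     rng_seed: int = 0) -> np.ndarray:
    """Run one image (3, S, S) or (S, S, 3) through a backbone.

    Returns the last convolutional feature map as (H, L, C).
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 3 and img.shape[0] != 3:
        img = img.transpose(2, 0, 1)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError(f"expected a (3, S, S) image, got shape {image.shape}")
    bb = build_backbone(backbone, np.random.default_rng(rng_seed))
    feat = bb(Tensor(img[None]))
    return feat.data[0].transpose(1, 2, 0)


def tokenize(X: np.ndarray, weight: np.ndarray, bias: np.ndarray,
             cls_vector: np.ndarray) -> np.ndarray:
    """Project a feature map X (H, L, C) with a 1x1 convolution and prepend CLS.

    ``weight`` is (C, D); returns the (HL+1, D) token matrix whose row 0 is
    ``cls_vector`` and whose row ``1 + r*L + c`` is the projection of
    feature-grid pixel (r, c) (row-major).
    """
    h, l, c = X.shape
    flat = X.reshape(h * l, c)
    tokens = flat @ weight + bias
    return np.concatenate([np.asarray(cls_vector)[None], tokens], axis=0)


def self_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                   return_weights: bool = False):
    """Scaled dot-product attention ``softmax(Q K^T / sqrt(D)) V``.

    Each output row is a convex combination of V's rows.  With
    ``return_weights=True`` also returns the row-stochastic weight matrix.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[0] != K.shape[0] or K.shape[0] != V.shape[0]:
        raise ValueError("Q, K, V must have equal numbers of rows")
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the inner dimension")
    d = Q.shape[-1]
    logits = Q @ K.T / np.sqrt(d)
    logits -= logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    out = w @ V
    return (out, w) if return_weights else out


def encoder_forward(tokens: np.ndarray, encoder: TransformerEncoder
                    ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply a stacked self-attention encoder to one token matrix (T, D).

    Returns the final token matrix and the per-layer attention trace
    (list of (T, T) row-stochastic matrices, first layer first).
    """
    out, trace = encoder(Tensor(tokens[None]))
    return out.data[0], [w[0] for w in trace]


def aggregate_and_classify(cls_vectors: list[np.ndarray], weight: np.ndarray,
                           bias: np.ndarray) -> np.ndarray:
    """Concatenate per-task CLS vectors and apply the two-node softmax head.

    Returns (p_healthy, p_MCI); ``weight`` is (sum(D), 2).
    """
    z = np.concatenate([np.asarray(v, dtype=float) for v in cls_vectors])
    logits = z @ weight + bias
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def pooling_baseline_forward(images: np.ndarray, tasks: tuple[str, ...],
                             backbone: str = "toy", rng_seed: int = 0
                             ) -> np.ndarray:
    """Forward one subject's images through an untrained pooling baseline.

    ``images`` is (n_tasks, 3, S, S); returns (p_healthy, p_MCI).
    """
    net = PoolingNet(tasks, backbone=backbone,
                     rng=np.random.default_rng(rng_seed))
    probs, _ = net.forward(np.asarray(images, dtype=np.float32)[None])
    return probs.data[0]
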