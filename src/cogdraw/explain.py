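"""Visual-explanation heat maps: attention rollout and Grad-CAM.

Attention rollout traces how the CLS token aggregates the feature-grid
tokens through the encoder stack.  Each layer's row-stochastic attention
matrix ``W_att`` is residual-compensated, ``A = 0.5 W_att + 0.5 I``, and the
per-layer raw attentions are multiplied recursively (later layers on the
left).  The CLS row of the result, restricted to the pixel tokens and
reshaped to the feature grid (row-major — the exact inverse of
tokenization), is upsampled bilinearly to the input resolution.

Grad-CAM serves the pooling baseline: channel gradients of the target-class
logit, averaged over the feature grid, weight the channels of the last
convolutional map; the rectified sum is upsampled to the input size.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .estimators import ConvAttClassifier, PoolingBaselineClassifier

__all__ = [
    "raw_attention", "attention_rollout", "cls_heatmap", "rollout_heatmaps",
    "grad_cam", "binarize_topk", "permute_heatmap",
]


def raw_attention(w_att: np.ndarray) -> np.ndarray:
    """Residual-compensated raw attention ``A = 0.5 W_att + 0.5 I``."""
    w_att = np.asarray(w_att, dtype=float)
    if w_att.ndim != 2 or w_att.shape[0] != w_att.shape[1]:
        raise ValueError(f"W_att must be square, got shape {w_att.shape}")
    return 0.5 * w_att + 0.5 * np.eye(w_att.shape[0])


def attention_rollout(trace: list[np.ndarray], from_layer: int = 0,
                      to_layer: int | None = None) -> np.ndarray:
    """Recursive rollout ``A(l_i) @ rollout(l_{i-1})`` over layers [j..i].

    ``trace`` holds per-layer attention matrices, first layer first.  The
    base case ``i = j`` returns ``A(l_j)`` itself.  The result is
    row-stochastic (a product of row-stochastic matrices).
    """
    if to_layer is None:
        to_layer = len(trace) - 1
    if from_layer > to_layer:
        raise ValueError(f"from_layer {from_layer} > to_layer {to_layer}")
    if to_layer >= len(trace):
        raise ValueError(f"to_layer {to_layer} out of range for "
                         f"{len(trace)}-layer trace")
    rollout = raw_attention(trace[from_layer])
    for i in range(from_layer + 1, to_layer + 1):
        rollout = raw_attention(trace[i]) @ rollout
    return rollout


def cls_heatmap(rollout: np.ndarray, grid_shape: tuple[int, int],
                input_size: int) -> np.ndarray:
    """CLS-row heat map at input resolution.

    Takes row 0 of the rollout (the CLS token), drops the CLS column,
    reshapes the HL pixel weights to (H, L) row-major and upsamples
    bilinearly to ``input_size`` x ``input_size``.
    """
    h, l = grid_shape
    if rollout.shape != (h * l + 1, h * l + 1):
        raise ValueError(f"rollout shape {rollout.shape} does not match "
                         f"grid {grid_shape} (expected {(h*l+1, h*l+1)})")
    grid = rollout[0, 1:].reshape(h, l)
    return resize(grid, (input_size, input_size), order=1, mode="edge",
                  anti_aliasing=False)


def rollout_heatmaps(model: ConvAttClassifier, X: np.ndarray
                     ) -> dict[str, np.ndarray]:
    """Per-task rollout heat maps for a batch.

    Returns ``{task: (n, S, S) array}``; rollout spans all encoder layers.
    """
    traces = model.attention_traces(X)
    size = X.shape[-1]
    grid = model.net_.grid_shape
    out = {}
    for task, trace in traces.items():
        n = trace[0].shape[0]
        maps = np.empty((n, size, size))
        for i in range(n):
            ro = attention_rollout([w[i] for w in trace])
            maps[i] = cls_heatmap(ro, grid, size)
        out[task] = maps
    return out


def grad_cam(model: PoolingBaselineClassifier, X: np.ndarray,
             target_class: int = 1) -> dict[str, np.ndarray]:
    """Grad-CAM heat maps of the pooling baseline, one per task pathway.

    Channel weights are the spatial means of the target-class logit's
    gradient on the last convolutional map; the weighted channel sum is
    rectified and bilinearly upsampled.  Defaults to the MCI logit.
    """
    if not isinstance(model, PoolingBaselineClassifier):
        raise TypeError("grad_cam applies to the pooling baseline; "
                        "use attention rollout for the Conv-Att model")
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 (healthy) or 1 (MCI)")
    model._require_fitted()
    X = model._check_X(X)
    net = model.net_
    net.zero_grad()
    net.forward(X)
    n, size = X.shape[0], X.shape[-1]
    seed = np.zeros_like(net.last_logits.data)
    seed[:, target_class] = 1.0
    net.last_logits.backward(seed)
    out = {}
    for t, task in enumerate(net.tasks):
        feat = net.last_features[t]
        weights = feat.grad.mean(axis=(2, 3))               # (n, C)
        cam = np.einsum("nc,nchw->nhw", weights, feat.data)
        cam = np.maximum(cam, 0.0)
        maps = np.empty((n, size, size))
        for i in range(n):
            maps[i] = resize(cam[i], (size, size), order=1, mode="edge",
                             anti_aliasing=False)
        out[task] = maps
    net.zero_grad()
    return out


def binarize_topk(heatmap: np.ndarray, k_percent: float) -> np.ndarray:
    """Top-k% binarization: 1 on the ``round(k/100 * n_pixels)`` highest
    pixels, 0 elsewhere; ties broken deterministically by linear pixel index
    (stable sort)."""
    if not 0 < k_percent <= 100:
        raise ValueError(f"k_percent must lie in (0, 100], got {k_percent}")
    hm = np.asarray(heatmap, dtype=float)
    n = hm.size
    k = int(round(k_percent / 100.0 * n))
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.argsort(-hm.ravel(), kind="stable")
        mask[order[:k]] = True
    return mask.reshape(hm.shape)


def permute_heatmap(heatmap: np.ndarray, rng: np.random.Generator,
                    grid_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Spatially shuffle a heat map (null model for localization tests).

    If ``grid_shape`` is given the map is permuted at the coarse feature-grid
    resolution it came from (block shuffle) and re-upsampled; otherwise the
    pixels are permuted directly.
    """
    hm = np.asarray(heatmap, dtype=float)
    if grid_shape is None:
        flat = hm.ravel().copy()
        rng.shuffle(flat)
        return flat.reshape(hm.shape)
    h, l = grid_shape
    coarse = resize(hm, (h, l), order=1, mode="edge", anti_aliasing=False)
    flat = coarse.ravel()
    flat = flat[rng.permutation(flat.size)]
    return resize(flat.reshape(h, l), hm.shape, order=1, mode="edge",
                  anti_aliasing=False)
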