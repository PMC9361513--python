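"""Classification metrics, repeated-split reports, and IoU-based
interpretability scoring.

Classification follows the p >= 0.5 MCI decision rule; AUC uses the
rank-based Mann-Whitney formulation with ties counted one half.
Interpretability compares top-k%-binarized heat maps against two kinds of
ground-truth regions of interest: *whole-drawing* ROIs (a dilated minimal
simple shape enclosing all ink) and *expert* ROIs (masks over anomalous or
omitted strokes — for synthetic cohorts, the generator's anomaly masks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.morphology import convex_hull_image, dilation, disk
from sklearn.base import clone
from sklearn.metrics import accuracy_score, f1_score

from .data import SubjectRecord, stratified_split
from .explain import binarize_topk, permute_heatmap
from .labels import hard_label

DEFAULT_K_VALUES = tuple(range(10, 81, 10))
DEFAULT_INK_THRESHOLD = 0.5
DEFAULT_ROI_MARGIN = 5

__all__ = [
    "MetricsReport", "auc_score", "classification_metrics",
    "repeated_splits_report", "whole_drawing_roi", "iou", "iou_curve",
    "rollout_vs_permuted", "report_ablation",
]


def auc_score(p, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 0.5.

    Invariant under strictly monotone transforms of ``p``; raises if only
    one class is present.
    """
    p = np.asarray(p, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(p)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def classification_metrics(p, labels) -> tuple[float, float, float]:
    """(accuracy, F1, AUC) of predicted MCI probabilities ``p``.

    Subjects with p >= 0.5 are classified as MCI (positive class for F1).
    """
    p = np.asarray(p, dtype=float)
    labels = np.asarray(labels)
    if p.shape != labels.shape:
        raise ValueError("p and labels must have the same length")
    pred = (p >= 0.5).astype(int)
    acc = float(accuracy_score(labels, pred))
    f1 = float(f1_score(labels, pred, pos_label=1, zero_division=0))
    return acc, f1, auc_score(p, labels)


@dataclass
class MetricsReport:
    """Per-split metrics with their mean and standard deviation."""

    per_split: pd.DataFrame            # columns: seed, accuracy, f1, auc

    @property
    def mean(self) -> pd.Series:
        return self.per_split[["accuracy", "f1", "auc"]].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_split[["accuracy", "f1", "auc"]].std(ddof=0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "std": self.std})


def repeated_splits_report(X, y, model, seeds, fractions=(0.70, 0.15, 0.15),
                           cutoff: int = 25) -> MetricsReport:
    """Train/evaluate once per split seed and summarize the metrics.

    ``X`` is the image array (n, n_tasks, 3, S, S); ``y`` the MoCA scores.
    Each repetition re-splits stratified by hard label with its own seed,
    clones and fits ``model`` on train (validating on validation), and
    scores on the unseen test partition.
    """
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("split seeds must be distinct")
    y = np.asarray(y)
    dummy = [SubjectRecord(subject_id=str(i), image_paths={}, moca_score=int(s))
             for i, s in enumerate(y)]
    rows = []
    for seed in seeds:
        split = stratified_split(dummy, fractions=fractions, seed=seed,
                                 cutoff=cutoff)
        part = np.array([split.assignment[str(i)] for i in range(len(y))])
        est = clone(model)
        est.set_params(random_state=seed)
        tr, va, te = (part == "train"), (part == "validation"), (part == "test")
        est.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        p = est.predict_proba(X[te])[:, 1]
        acc, f1, auc = classification_metrics(
            p, np.asarray(hard_label(y[te], cutoff=cutoff)))
        rows.append({"seed": seed, "accuracy": acc, "f1": f1, "auc": auc})
    return MetricsReport(per_split=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# regions of interest and IoU
# ---------------------------------------------------------------------------

def _mvee(points: np.ndarray, tol: float = 1e-3):
    """Khachiyan minimum-volume enclosing ellipse of 2-D points.

    Returns (center, shape matrix A) with the ellipse {x: (x-c)' A (x-c) <= 1}.
    """
    pts = points.astype(float)
    n, d = pts.shape
    q = np.column_stack([pts, np.ones(n)]).T
    u = np.full(n, 1.0 / n)
    for _ in range(1000):
        x = q @ (u[:, None] * q.T)
        m = np.einsum("ij,ji->i", q.T, np.linalg.solve(x, q))
        j = int(np.argmax(m))
        step = (m[j] - d - 1) / ((d + 1) * (m[j] - 1))
        new_u = (1 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    center = pts.T @ u
    cov = pts.T @ (u[:, None] * pts) - np.outer(center, center)
    a = np.linalg.inv(cov) / d
    return center, a


def whole_drawing_roi(image: np.ndarray, shape_kind: str = "circle",
                      margin_px: int = DEFAULT_ROI_MARGIN,
                      ink_threshold: float = DEFAULT_INK_THRESHOLD) -> np.ndarray:
    """Dilated minimal enclosing simple shape around all drawn (ink) pixels.

    ``image`` is a white-background drawing (uint8 or float in [0, 1]); ink
    is intensity below ``ink_threshold`` of full white.  ``shape_kind`` is
    one of ``circle`` (minimum bounding circle), ``ellipse``
    (minimum-volume enclosing ellipse) or ``polygon`` (convex hull); the
    fitted shape is enlarged by ``margin_px`` via morphological dilation.
    """
    img = np.asarray(image, dtype=float)
    if img.max() > 1.5:
        img = img / 255.0
    ink = img < ink_threshold
    if not ink.any():
        raise ValueError("blank image: no ink pixels below the threshold")
    pts = np.column_stack(np.nonzero(ink)).astype(float)
    rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]]

    if shape_kind == "polygon":
        mask = convex_hull_image(ink)
    elif shape_kind == "circle":
        import shapely
        from shapely.geometry import MultiPoint
        mbc = shapely.minimum_bounding_circle(MultiPoint(pts))
        # point coords were passed as (row, col), so x is the row axis
        cy, cx = mbc.centroid.x, mbc.centroid.y
        radius = 0.0
        if mbc.geom_type != "Point":
            b = mbc.bounds
            radius = (b[2] - b[0]) / 2.0
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2
    elif shape_kind == "ellipse":
        try:
            center, a = _mvee(pts)
            dr = rr - center[0]
            dc = cc - center[1]
            quad = (a[0, 0] * dr * dr + 2 * a[0, 1] * dr * dc
                    + a[1, 1] * dc * dc)
            mask = quad <= 1.0 + 1e-9
        except np.linalg.LinAlgError:   # degenerate (collinear) ink
            mask = convex_hull_image(ink)
    else:
        raise ValueError("shape_kind must be 'circle', 'ellipse' or 'polygon'")

    mask |= ink  # guarantee enclosure under rasterization
    if margin_px > 0:
        mask = dilation(mask, footprint=disk(margin_px))
    return mask.astype(bool)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B|; 0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def iou_curve(heatmaps, roi_masks, k_values=DEFAULT_K_VALUES) -> pd.DataFrame:
    """Mean +- std IoU between top-k%-binarized heat maps and ROI masks.

    ``heatmaps`` and ``roi_masks`` are paired sequences (or stacked arrays)
    of equal length; returns one row per k with columns
    (k, mean_iou, std_iou, n).
    """
    heatmaps = list(heatmaps)
    roi_masks = list(roi_masks)
    if len(heatmaps) != len(roi_masks) or not heatmaps:
        raise ValueError("heatmaps and roi_masks must be nonempty and paired")
    rows = []
    for k in k_values:
        vals = [iou(binarize_topk(h, k), m)
                for h, m in zip(heatmaps, roi_masks)]
        rows.append({"k": k, "mean_iou": float(np.mean(vals)),
                     "std_iou": float(np.std(vals)), "n": len(vals)})
    return pd.DataFrame(rows)


def rollout_vs_permuted(heatmaps, masks, k_percent: float = 20.0,
                        rng: np.random.Generator | None = None,
                        grid_shape: tuple[int, int] | None = None,
                        n_permutations: int = 10) -> dict:
    """Paired localization test of heat maps against anomaly masks.

    For every pair with a nonempty mask, compares the top-k% IoU of the
    heat map with the per-image permutation null (the IoU of spatially
    permuted copies, averaged over ``n_permutations`` seeded draws).
    Returns mean IoUs, the fraction of pairs the real map wins, and the
    number of pairs.
    """
    rng = rng or np.random.default_rng(0)
    real, perm = [], []
    for hm, mask in zip(heatmaps, masks):
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            continue
        real.append(iou(binarize_topk(hm, k_percent), mask))
        perm.append(np.mean([
            iou(binarize_topk(permute_heatmap(hm, rng, grid_shape=grid_shape),
                              k_percent), mask)
            for _ in range(n_permutations)]))
    real, perm = np.array(real), np.array(perm)
    if len(real) == 0:
        raise ValueError("no pairs with nonempty masks")
    return {"mean_iou": float(real.mean()),
            "mean_iou_permuted": float(perm.mean()),
            "win_fraction": float(np.mean(real > perm)),
            "n_pairs": int(len(real))}


def report_ablation(metric_rows: pd.DataFrame, baseline: str,
                    name_col: str = "model") -> pd.DataFrame:
    """Absolute and relative deltas of every row against a baseline row.

    For each numeric metric column: ``delta = value - baseline`` and
    ``relative = delta / baseline`` (reported as a percentage).
    """
    if baseline not in metric_rows[name_col].values:
        raise ValueError(f"baseline row {baseline!r} not found")
    base = metric_rows.loc[metric_rows[name_col] == baseline].iloc[0]
    out = metric_rows.copy()
    for col in metric_rows.columns:
        if col == name_col or not np.issubdtype(metric_rows[col].dtype,
                                                np.number):
            continue
        out[f"{col}_delta"] = metric_rows[col] - base[col]
        out[f"{col}_rel_pct"] = 100.0 * (metric_rows[col] - base[col]) / base[col]
    return out
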