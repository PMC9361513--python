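import itertools

import numpy as np
import pandas as pd
import pytest
from skimage.morphology import disk

from cogdraw import ConvAttClassifier
from cogdraw.evaluate import (auc_score, classification_metrics, iou,
                              iou_curve, repeated_splits_report,
                              report_ablation, rollout_vs_permuted,
                              whole_drawing_roi)
from cogdraw.explain import binarize_topk


# -- independent oracles -----------------------------------------------------

def _metrics_oracle(p, labels):
    pred = [1 if pi >= 0.5 else 0 for pi in p]
    tp = sum(1 for a, b in zip(pred, labels) if a == 1 and b == 1)
    fp = sum(1 for a, b in zip(pred, labels) if a == 1 and b == 0)
    fn = sum(1 for a, b in zip(pred, labels) if a == 0 and b == 1)
    acc = np.mean([a == b for a, b in zip(pred, labels)])
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    num, den = 0.0, 0
    for (pi, yi), (pj, yj) in itertools.product(zip(p, labels), repeat=2):
        if yi == 1 and yj == 0:
            den += 1
            num += 1.0 if pi > pj else (0.5 if pi == pj else 0.0)
    return acc, f1, num / den


def test_metrics_perfect_predictor():
    labels = np.array([1, 0, 1, 0])
    assert classification_metrics(labels.astype(float), labels) == (1, 1, 1)


def test_metrics_worked_example():
    acc, f1, auc = classification_metrics(
        np.array([0.9, 0.6, 0.4, 0.1]), np.array([1, 0, 1, 0]))
    assert acc == pytest.approx(0.5)
    assert auc == pytest.approx(0.75)


def test_boundary_probability_counts_as_mci():
    acc, _, _ = classification_metrics(np.array([0.5, 0.1]),
                                       np.array([1, 0]))
    assert acc == 1.0


def test_metrics_match_exhaustive_oracle_on_all_labelings():
    rng = np.random.default_rng(0)
    for n in (4, 5, 6):
        p = np.round(rng.random(n), 2)
        for bits in itertools.product([0, 1], repeat=n):
            labels = np.array(bits)
            if labels.min() == labels.max():
                with pytest.raises(ValueError):
                    classification_metrics(p, labels)
                continue
            got = classification_metrics(p, labels)
            exp = _metrics_oracle(p, labels)
            assert got == pytest.approx(exp, abs=1e-12)


def test_auc_agrees_with_sklearn_and_is_monotone_invariant():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(1)
    for _ in range(20):
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            continue
        p = np.round(rng.random(30), 1)  # coarse grid forces ties
        assert auc_score(p, labels) == pytest.approx(
            roc_auc_score(labels, p), abs=1e-12)
        assert auc_score(np.exp(3 * p), labels) == pytest.approx(
            auc_score(p, labels), abs=1e-12)


# -- IoU ---------------------------------------------------------------------

def test_iou_basic_cases():
    a = np.zeros((4, 4), bool)
    a[0, :2] = True
    b = np.zeros((4, 4), bool)
    b[0, 1] = b[1, 1] = True
    assert iou(a, a) == 1.0
    assert iou(a, ~a) == 0.0
    assert iou(a, b) == pytest.approx(1 / 3)
    assert iou(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 0.0
    with pytest.raises(ValueError):
        iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def test_iou_matches_pixel_enumeration_on_random_masks():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a = rng.random((16, 16)) > 0.6
        b = rng.random((16, 16)) > 0.6
        inter = sum(1 for i in range(16) for j in range(16)
                    if a[i, j] and b[i, j])
        union = sum(1 for i in range(16) for j in range(16)
                    if a[i, j] or b[i, j])
        expected = inter / union if union else 0.0
        assert iou(a, b) == pytest.approx(expected, abs=1e-12)
        assert iou(a, b) == iou(b, a)


# -- whole-drawing ROI -------------------------------------------------------

def test_roi_single_pixel_circle_is_margin_disc():
    img = np.ones((21, 21))
    img[10, 10] = 0.0
    mask = whole_drawing_roi(img, "circle", margin_px=2)
    expected = np.zeros((21, 21), bool)
    expected[8:13, 8:13] = disk(2).astype(bool)
    assert np.array_equal(mask, expected)


@pytest.mark.parametrize("shape_kind", ["circle", "ellipse", "polygon"])
def test_roi_always_covers_ink(shape_kind):
    from cogdraw.synthetic import make_base_drawing
    img = make_base_drawing("cube", 64, rng_seed=0)
    mask = whole_drawing_roi(img, shape_kind, margin_px=3)
    ink = img < 128
    assert (mask | ~ink).all()


def test_roi_margin_monotone():
    from cogdraw.synthetic import make_base_drawing
    img = make_base_drawing("clock", 64, rng_seed=0)
    m2 = whole_drawing_roi(img, "circle", margin_px=2)
    m4 = whole_drawing_roi(img, "circle", margin_px=4)
    assert (m4 | ~m2).all() and m4.sum() > m2.sum()


def test_roi_blank_image_raises():
    with pytest.raises(ValueError, match="blank"):
        whole_drawing_roi(np.ones((16, 16)))


# -- IoU curves --------------------------------------------------------------

def test_iou_curve_perfect_localization():
    roi = np.zeros((8, 8), bool)
    roi.ravel()[:16] = True          # 25% of pixels, first by linear index
    table = iou_curve([roi.astype(float)], [roi], k_values=[25])
    assert table.mean_iou.iloc[0] == 1.0


def test_iou_curve_row_count_matches_k_values():
    rng = np.random.default_rng(0)
    hm = [rng.random((8, 8)) for _ in range(3)]
    rois = [rng.random((8, 8)) > 0.5 for _ in range(3)]
    table = iou_curve(hm, rois, k_values=list(range(10, 81, 10)))
    assert len(table) == 8
    assert (table.n == 3).all()


def test_iou_curve_random_heatmap_hypergeometric_expectation():
    """Random heat map vs ROI of fraction f: E[IoU at k=f*100] concentrates
    near f*k' / (f + k' - f*k')."""
    rng = np.random.default_rng(3)
    f = 0.25
    n = 16 * 16
    roi = np.zeros(n, bool)
    roi[rng.choice(n, int(f * n), replace=False)] = True
    roi = roi.reshape(16, 16)
    vals = [iou(binarize_topk(rng.random((16, 16)), 25), roi)
            for _ in range(300)]
    kp = 0.25
    expected = f * kp / (f + kp - f * kp)
    assert np.mean(vals) == pytest.approx(expected, abs=0.02)


def test_iou_curve_empty_pairing_raises():
    with pytest.raises(ValueError):
        iou_curve([], [])


def test_rollout_vs_permuted_perfect_heatmap_wins():
    rng = np.random.default_rng(4)
    hms, masks = [], []
    for _ in range(12):
        m = np.zeros((20, 20), bool)
        r, c = rng.integers(0, 16, 2)
        m[r:r + 4, c:c + 4] = True
        hms.append(m.astype(float))
        masks.append(m)
    res = rollout_vs_permuted(hms, masks, k_percent=4.0, rng=rng)
    assert res["n_pairs"] == 12
    assert res["mean_iou"] == pytest.approx(1.0)
    assert res["win_fraction"] > 0.9
    with pytest.raises(ValueError):
        rollout_vs_permuted([np.ones((4, 4))], [np.zeros((4, 4), bool)])


# -- repeated splits ---------------------------------------------------------

def test_repeated_splits_report_summary(small_cohort):
    _, X, y = small_cohort
    model = ConvAttClassifier.toy(epochs=1, random_state=0)
    report = repeated_splits_report(X, y, model, seeds=[0, 1])
    assert len(report.per_split) == 2
    for metric in ("accuracy", "f1", "auc"):
        lo, hi = report.per_split[metric].min(), report.per_split[metric].max()
        assert lo <= report.mean[metric] <= hi
        assert report.std[metric] >= 0
    with pytest.raises(ValueError, match="distinct"):
        repeated_splits_report(X, y, model, seeds=[0, 0])


def test_single_repeat_has_zero_std(small_cohort):
    _, X, y = small_cohort
    model = ConvAttClassifier.toy(epochs=1, random_state=0)
    report = repeated_splits_report(X, y, model, seeds=[3])
    assert (report.std == 0).all()


# -- ablation reporting ------------------------------------------------------

def test_report_ablation_deltas_and_missing_baseline():
    rows = pd.DataFrame({"model": ["baseline", "proposed"],
                         "accuracy": [0.7478, 0.8116]})
    out = report_ablation(rows, "baseline")
    assert out.accuracy_delta.iloc[0] == 0.0
    assert out.accuracy_rel_pct.iloc[1] == pytest.approx(8.53, abs=0.005)
    with pytest.raises(ValueError):
        report_ablation(rows, "nope")
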