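import numpy as np
import pytest
from skimage.transform import resize

from cogdraw import PoolingBaselineClassifier
from cogdraw.explain import (attention_rollout, binarize_topk, cls_heatmap,
                             grad_cam, permute_heatmap, raw_attention,
                             rollout_heatmaps)


def _random_row_stochastic(n, rng):
    w = rng.random((n, n))
    return w / w.sum(axis=1, keepdims=True)


# -- raw attention -----------------------------------------------------------

def test_raw_attention_identity_fixed_point():
    assert np.allclose(raw_attention(np.eye(5)), np.eye(5))


def test_raw_attention_uniform_two_by_two():
    a = raw_attention(np.full((2, 2), 0.5))
    assert np.allclose(a, [[0.75, 0.25], [0.25, 0.75]])


def test_raw_attention_preserves_row_sums():
    rng = np.random.default_rng(0)
    a = raw_attention(_random_row_stochastic(9, rng))
    assert np.allclose(a.sum(axis=1), 1.0, atol=1e-12)


def test_raw_attention_rejects_non_square():
    with pytest.raises(ValueError):
        raw_attention(np.zeros((3, 4)))


# -- rollout -----------------------------------------------------------------

def test_rollout_base_case_is_single_raw_attention():
    rng = np.random.default_rng(1)
    w = _random_row_stochastic(6, rng)
    assert np.allclose(attention_rollout([w], 0, 0), raw_attention(w))


def test_rollout_identity_chain():
    trace = [np.eye(7)] * 4
    assert np.allclose(attention_rollout(trace), np.eye(7))


def test_rollout_matches_explicit_ordered_product():
    rng = np.random.default_rng(2)
    trace = [_random_row_stochastic(5, rng) for _ in range(3)]
    got = attention_rollout(trace)
    a = [raw_attention(w) for w in trace]
    assert np.allclose(got, a[2] @ a[1] @ a[0], atol=1e-6)


def test_rollout_rejects_bad_layer_range():
    trace = [np.eye(3)] * 2
    with pytest.raises(ValueError):
        attention_rollout(trace, from_layer=1, to_layer=0)
    with pytest.raises(ValueError):
        attention_rollout(trace, to_layer=5)


# -- CLS heat map ------------------------------------------------------------

def test_cls_heatmap_uniform_row_gives_constant_map():
    n = 17
    ro = np.full((n, n), 1.0 / n)
    hm = cls_heatmap(ro, (4, 4), 64)
    assert hm.shape == (64, 64)
    assert np.allclose(hm, hm.flat[0])


def test_cls_heatmap_mass_on_first_pixel_peaks_top_left():
    n = 17
    ro = np.zeros((n, n))
    ro[0, 1] = 1.0  # all CLS mass on the token of pixel (0, 0)
    hm = cls_heatmap(ro, (4, 4), 64)
    r, c = np.unravel_index(np.argmax(hm), hm.shape)
    assert r < 16 and c < 16


def test_cls_heatmap_row_major_reshape_convention():
    ro = np.zeros((5, 5))
    ro[0, 1:] = [0.1, 0.2, 0.3, 0.4]
    hm = cls_heatmap(ro, (2, 2), 2)  # no upsampling at input_size 2
    assert np.allclose(hm, [[0.1, 0.2], [0.3, 0.4]])


def test_cls_heatmap_shape_mismatch_raises():
    with pytest.raises(ValueError):
        cls_heatmap(np.zeros((6, 6)), (4, 4), 64)


def test_heatmap_reshape_inverts_tokenization():
    """Pixel (r, c) -> token 1 + r*L + c -> heat cell (r, c) round-trips."""
    h, l = 3, 4
    n = h * l + 1
    for r, c in [(0, 0), (1, 2), (2, 3)]:
        ro = np.zeros((n, n))
        ro[0, 1 + r * l + c] = 1.0
        hm = cls_heatmap(ro, (h, l), max(h, l))
        grid = ro[0, 1:].reshape(h, l)
        assert grid[r, c] == 1.0 and grid.sum() == 1.0
        assert hm.max() > 0


# -- top-k binarization ------------------------------------------------------

def test_topk_full_selection():
    assert binarize_topk(np.random.default_rng(0).random((8, 8)), 100).all()


def test_topk_order_statistic():
    mask = binarize_topk(np.array([[1.0, 2.0], [3.0, 4.0]]), 50)
    assert np.array_equal(mask, [[False, False], [True, True]])


def test_topk_tie_break_by_pixel_index():
    mask = binarize_topk(np.ones((4, 4)), 25)
    assert mask.sum() == 4
    assert mask.ravel()[:4].all()


@pytest.mark.parametrize("k", range(10, 81, 10))
def test_topk_cardinality_exact(k):
    rng = np.random.default_rng(k)
    for shape in [(10, 10), (13, 7), (64, 64)]:
        hm = rng.random(shape)
        assert binarize_topk(hm, k).sum() == round(k / 100 * hm.size)


def test_topk_rejects_bad_k():
    for k in (0, -5, 101):
        with pytest.raises(ValueError):
            binarize_topk(np.ones((4, 4)), k)


# -- permutation null --------------------------------------------------------

def test_permute_heatmap_preserves_values():
    rng = np.random.default_rng(0)
    hm = rng.random((16, 16))
    out = permute_heatmap(hm, rng)
    assert sorted(out.ravel()) == pytest.approx(sorted(hm.ravel()))
    assert not np.array_equal(out, hm)


# -- model-level explanations ------------------------------------------------

def test_rollout_heatmaps_shapes_and_nonnegativity(trained_toy, small_cohort):
    _, X, _ = small_cohort
    maps = rollout_heatmaps(trained_toy, X[:4])
    assert set(maps) == {"clock", "cube", "trail"}
    for stack in maps.values():
        assert stack.shape == (4, 64, 64)
        assert np.isfinite(stack).all() and (stack >= 0).all()


@pytest.fixture(scope="module")
def trained_pooling(small_cohort):
    _, X, y = small_cohort
    est = PoolingBaselineClassifier.toy(epochs=2, random_state=0)
    est.fit(X[:40], y[:40])
    return est


def test_grad_cam_rejects_conv_att(trained_toy, small_cohort):
    _, X, _ = small_cohort
    with pytest.raises(TypeError):
        grad_cam(trained_toy, X[:2])


def test_grad_cam_nonnegative_and_task_keyed(trained_pooling, small_cohort):
    _, X, _ = small_cohort
    maps = grad_cam(trained_pooling, X[:3], target_class=1)
    assert set(maps) == {"clock", "cube", "trail"}
    for stack in maps.values():
        assert stack.shape == (3, 64, 64)
        assert (stack >= 0).all()


def test_grad_cam_zero_gradients_give_zero_maps(trained_pooling, small_cohort):
    _, X, _ = small_cohort
    import copy
    est = copy.deepcopy(trained_pooling)
    est.net_.head.weight.data[:] = 0.0  # constant logits -> zero gradients
    maps = grad_cam(est, X[:2])
    for stack in maps.values():
        assert np.allclose(stack, 0.0)


def test_grad_cam_matches_analytic_gap_gradient(trained_pooling, small_cohort):
    """For GAP + linear head, d logit_c / d feat[ch, i, j] = W[ch, c] / (H*L);
    the hand-evaluated weighted rectified sum must match."""
    _, X, _ = small_cohort
    est = trained_pooling
    maps = grad_cam(est, X[:2], target_class=1)
    net = est.net_
    net.forward(X[:2].astype(np.float32))
    c_per = net.backbones[0].out_channels
    for t, task in enumerate(net.tasks):
        feat = net.last_features[t].data           # (2, C, H, L)
        _, C, H, L = feat.shape
        w_block = net.head.weight.data[t * c_per:(t + 1) * c_per, 1]
        alphas = w_block / (H * L)                 # analytic channel weights
        for i in range(2):
            cam = np.maximum(np.einsum("c,chw->hw", alphas, feat[i]), 0)
            expected = resize(cam, (64, 64), order=1, mode="edge",
                              anti_aliasing=False)
            assert np.allclose(maps[task][i], expected, atol=1e-4)
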