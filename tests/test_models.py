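import numpy as np
import pytest

from cogdraw.models import (ConvAttNet, PoolingNet, aggregate_and_classify,
                            backbone_forward, pooling_baseline_forward,
                            self_attention, tokenize)
from cogdraw.nn import TransformerEncoder, Tensor
from cogdraw.models import encoder_forward


# -- backbones ---------------------------------------------------------------

def test_vgg16_stride_arithmetic_at_256_and_64():
    f = backbone_forward(np.random.default_rng(0)
                         .random((3, 256, 256)).astype(np.float32), "vgg16")
    assert f.shape == (8, 8, 512)
    f = backbone_forward(np.zeros((3, 64, 64), dtype=np.float32), "vgg16")
    assert f.shape == (2, 2, 512)
    assert np.isfinite(f).all()


def test_toy_backbone_shape_and_bad_inputs():
    f = backbone_forward(np.zeros((3, 64, 64), dtype=np.float32), "toy")
    assert f.shape == (4, 4, 32)
    with pytest.raises(ValueError):
        backbone_forward(np.zeros((64, 64), dtype=np.float32), "toy")
    with pytest.raises(ValueError, match="toy"):
        backbone_forward(np.zeros((3, 64, 64), dtype=np.float32), "resnet")


# -- tokenization ------------------------------------------------------------

def test_tokenize_row_major_convention_and_identity_projection():
    h, l, c = 2, 3, 4
    X = np.random.default_rng(0).normal(0, 1, (h, l, c))
    cls = np.zeros(c)
    tok = tokenize(X, np.eye(c), np.zeros(c), cls)
    assert tok.shape == (h * l + 1, c)
    assert np.array_equal(tok[0], cls)
    # token of pixel (r, c) sits at row 1 + r*L + c
    assert np.allclose(tok[1 + 1 * l + 2], X[1, 2])
    assert np.allclose(tok[1:], X.reshape(h * l, c))


def test_tokenize_smallest_grid():
    tok = tokenize(np.ones((1, 1, 2)), np.eye(2), np.zeros(2), np.zeros(2))
    assert tok.shape == (2, 2)


# -- attention ---------------------------------------------------------------

def test_attention_singleton_softmax_returns_value():
    q = np.random.default_rng(0).normal(0, 1, (1, 3))
    v = np.array([[2.0, -1.0, 0.5]])
    assert np.allclose(self_attention(q, q, v), v)


def test_attention_zero_query_gives_column_mean():
    k = np.random.default_rng(1).normal(0, 1, (4, 3))
    v = np.arange(12, dtype=float).reshape(4, 3)
    out, w = self_attention(np.zeros((4, 3)), k, v, return_weights=True)
    assert np.allclose(w, 0.25)
    assert np.allclose(out, np.tile(v.mean(axis=0), (4, 1)))


def test_attention_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    q, k, v = (rng.normal(0, 1, (4, 3)) for _ in range(3))
    out, w = self_attention(q, k, v, return_weights=True)
    # step-by-step: logits, rowwise softmax, weighted sum
    expected = np.zeros_like(out)
    for i in range(4):
        logits = np.array([q[i] @ k[j] / np.sqrt(3) for j in range(4)])
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        expected[i] = sum(a[j] * v[j] for j in range(4))
    assert np.allclose(out, expected, atol=1e-6)
    assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)


def test_attention_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        self_attention(np.zeros((3, 2)), np.zeros((4, 2)), np.zeros((4, 2)))
    with pytest.raises(ValueError):
        self_attention(np.zeros((3, 2)), np.zeros((3, 5)), np.zeros((3, 2)))


# -- encoder -----------------------------------------------------------------

def test_encoder_trace_counts_layers_and_rows_are_stochastic():
    rng = np.random.default_rng(0)
    enc = TransformerEncoder(1, 8, 16, rng)
    tokens = rng.normal(0, 1, (5, 8)).astype(np.float32)
    out, trace = encoder_forward(tokens, enc)
    assert len(trace) == 1
    assert out.shape == tokens.shape
    enc3 = TransformerEncoder(3, 8, 16, rng)
    _, trace3 = encoder_forward(tokens, enc3)
    assert len(trace3) == 3
    for w in trace3:
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)


def test_encoder_residual_path_with_zeroed_sublayers():
    rng = np.random.default_rng(0)
    enc = TransformerEncoder(1, 6, 12, rng)
    layer = enc.layers[0]
    layer.wv.weight.data[:] = 0
    layer.wv.bias.data[:] = 0
    layer.ffn2.weight.data[:] = 0
    layer.ffn2.bias.data[:] = 0
    # pre-normalized rows pass through the residual + LN stack unchanged
    x = rng.normal(0, 1, (4, 6))
    x = (x - x.mean(-1, keepdims=True)) / x.std(-1, keepdims=True)
    out, _ = encoder_forward(x.astype(np.float32), enc)
    assert np.allclose(out, x, atol=1e-3)


def test_encoder_rejects_zero_layers():
    with pytest.raises(ValueError):
        TransformerEncoder(0, 8, 16, np.random.default_rng(0))


# -- classification head -----------------------------------------------------

def test_softmax_head_closed_forms_and_shift_invariance():
    d = 4
    w = np.zeros((3 * d, 2))
    # zero weights, zero bias -> logits (0, 0) -> (0.5, 0.5)
    p = aggregate_and_classify([np.ones(d)] * 3, w, np.zeros(2))
    assert np.allclose(p, [0.5, 0.5])
    # logits (1, 0)
    p = aggregate_and_classify([np.zeros(d)] * 3, w, np.array([1.0, 0.0]))
    assert p[0] == pytest.approx(0.73106, abs=1e-5)
    assert p[1] == pytest.approx(0.26894, abs=1e-5)
    # adding a constant to both logits changes nothing
    p2 = aggregate_and_classify([np.zeros(d)] * 3, w, np.array([4.0, 3.0]))
    assert np.allclose(p, p2, atol=1e-6)
    assert p.sum() == pytest.approx(1.0)


# -- full networks -----------------------------------------------------------

def test_conv_att_forward_probabilities_and_trace_shapes():
    net = ConvAttNet(("clock", "cube", "trail"), backbone="toy", n_layers=2,
                     hidden_dim=16, ffn_dim=32, rng=np.random.default_rng(0))
    x = np.random.default_rng(1).random((2, 3, 3, 64, 64)).astype(np.float32)
    probs, traces = net.forward(x)
    assert probs.data.shape == (2, 2)
    assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)
    assert net.grid_shape == (4, 4)
    for task in ("clock", "cube", "trail"):
        assert len(traces[task]) == 2
        assert traces[task][0].shape == (2, 17, 17)
        assert np.allclose(traces[task][0].sum(axis=-1), 1.0, atol=1e-6)


def test_conv_att_pathway_permutation_consistency():
    """Permuting the pathways together with their inputs leaves p unchanged."""
    rng_seed = 3
    net = ConvAttNet(("clock", "cube", "trail"), backbone="toy", n_layers=1,
                     hidden_dim=8, ffn_dim=16,
                     rng=np.random.default_rng(rng_seed))
    x = np.random.default_rng(4).random((2, 3, 3, 64, 64)).astype(np.float32)
    p_ref, _ = net.forward(x)
    perm = [2, 0, 1]
    net.pathways = [net.pathways[i] for i in perm]
    d = net.hidden_dim
    blocks = [net.head.weight.data[i * d:(i + 1) * d] for i in perm]
    net.head.weight.data = np.concatenate(blocks, axis=0)
    p_perm, _ = net.forward(x[:, perm])
    assert np.allclose(p_ref.data, p_perm.data, atol=1e-5)


def test_forward_rejects_wrong_shapes():
    net = ConvAttNet(("clock",), backbone="toy", hidden_dim=8, ffn_dim=16,
                     rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        net.forward(np.zeros((2, 3, 3, 64, 64), dtype=np.float32))


def test_pooling_baseline_single_and_multi_input():
    p = pooling_baseline_forward(
        np.zeros((1, 3, 64, 64), dtype=np.float32), ("clock",), "toy")
    assert p.shape == (2,) and p.sum() == pytest.approx(1.0)
    net = PoolingNet(("clock", "cube", "trail"), backbone="toy",
                     rng=np.random.default_rng(0))
    # concatenated pooled vector has length 3C ahead of the two-node head
    assert net.head.weight.shape == (3 * 32, 2)
    probs, _ = net.forward(
        np.random.default_rng(0).random((2, 3, 3, 64, 64)).astype(np.float32))
    assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)


def test_global_average_pooling_of_constant_map_is_that_constant():
    net = PoolingNet(("clock",), backbone="toy", rng=np.random.default_rng(0))
    feat = Tensor(np.full((1, 32, 4, 4), 2.5, dtype=np.float32))
    assert np.allclose(feat.mean(axis=(2, 3)).data, 2.5)
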