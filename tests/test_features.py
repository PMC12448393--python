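"""Oracle tests for the dual-pathway network.

The reference implementations here are deliberately straight-line: explicit
loops over queries, keys, heads, positions and kernel taps, no shared code
with the package internals.
"""

import math

import numpy as np
import pytest

from ecfuse.features import (
    ModelConfig,
    attention_importance,
    cross_attention,
    extract_features,
    gfe_block,
    importance_from_weights,
    init_extractor_params,
    lfe_block,
    scaled_dot_attention,
)
from ecfuse.io import EmbeddingPair


# ----------------------------------------------------------- reference oracles
def ref_attention(Q, K, V):
    Lq, d = Q.shape
    Lk, dv = K.shape[0], V.shape[1]
    out = np.zeros((Lq, dv))
    weights = np.zeros((Lq, Lk))
    for i in range(Lq):
        logits = [sum(Q[i, t] * K[j, t] for t in range(d)) / math.sqrt(d) for j in range(Lk)]
        m = max(logits)
        exps = [math.exp(l - m) for l in logits]
        z = sum(exps)
        for j in range(Lk):
            weights[i, j] = exps[j] / z
            for t in range(dv):
                out[i, t] += weights[i, j] * V[j, t]
    return out, weights


def ref_layer_norm(x, gamma, beta, eps=1e-5):
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        mu = x[i].mean()
        var = x[i].var()
        out[i] = (x[i] - mu) / math.sqrt(var + eps) * gamma + beta
    return out


def _d(p):
    return p.data


def ref_cross_attention(query, kv, params):
    heads = []
    ws = []
    for wq, wk, wv in zip(params["Wq"], params["Wk"], params["Wv"]):
        o, w = ref_attention(query @ _d(wq), kv @ _d(wk), kv @ _d(wv))
        heads.append(o)
        ws.append(w)
    mixed = np.concatenate(heads, axis=-1) @ _d(params["Wo"]) + _d(params["bo"])
    return ref_layer_norm(query + mixed, _d(params["ln_gamma"]), _d(params["ln_beta"])), np.stack(ws)


def ref_conv1d_same(x, w, b):
    L, c_in = x.shape
    k, _, c_out = w.shape
    pad = k // 2
    out = np.zeros((L, c_out))
    for pos in range(L):
        for o in range(c_out):
            acc = b[o]
            for tap in range(k):
                src = pos + tap - pad
                if 0 <= src < L:
                    for c in range(c_in):
                        acc += x[src, c] * w[tap, c, o]
            out[pos, o] = acc
    return out


def ref_lfe(chan_a, chan_b, block):
    x = np.concatenate([chan_a, chan_b], axis=-1)
    branches = [
        ref_conv1d_same(x, _d(block["convs"][k]["w"]), _d(block["convs"][k]["b"]))
        for k in block["convs"]
    ]
    cat = np.concatenate(branches, axis=-1)
    mlp = block["mlp"]
    hidden = np.maximum(cat @ _d(mlp["W1"]) + _d(mlp["b1"]), 0.0)
    return hidden @ _d(mlp["W2"]) + _d(mlp["b2"])


def ref_extract(seq, tdi, params, cfg):
    seq_hats = []
    cur_seq, cur_tdi = seq, tdi
    w2 = None
    for i in range(cfg.n_blocks):
        tdi_hat, _ = ref_cross_attention(cur_tdi, cur_seq, params["gfe"][i]["layer1"])
        seq_hat, w2 = ref_cross_attention(cur_seq, tdi_hat, params["gfe"][i]["layer2"])
        cur_seq, cur_tdi = seq_hat, tdi_hat
        seq_hats.append(seq_hat)
    chan_a, chan_b = seq, tdi
    local = None
    for i in range(cfg.n_blocks):
        if i > 0:
            chan_a, chan_b = seq_hats[i - 1], local
        local = ref_lfe(chan_a, chan_b, params["lfe"][i])
    fused = np.concatenate([seq_hats[-1], local], axis=-1)
    return fused, fused.mean(axis=0), w2


# ----------------------------------------------------------------- attention
def test_single_key_attention_returns_the_value_row():
    rng = np.random.default_rng(0)
    q = rng.normal(size=(4, 3))
    v = rng.normal(size=(1, 5))
    out = scaled_dot_attention(q, rng.normal(size=(1, 3)), v)
    np.testing.assert_allclose(out, np.repeat(v, 4, axis=0), atol=1e-12)


def test_equal_logits_average_the_values():
    # queries orthogonal to both keys -> equal logits -> mean of value rows
    q = np.array([[0.0, 0.0, 1.0]])
    k = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    v = np.array([[2.0, 0.0], [0.0, 4.0]])
    np.testing.assert_allclose(scaled_dot_attention(q, k, v), [[1.0, 2.0]], atol=1e-12)


def test_attention_matches_nested_loop_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        q = rng.normal(size=(3, 4))
        k = rng.normal(size=(5, 4))
        v = rng.normal(size=(5, 4))
        expected, weights = ref_attention(q, k, v)
        np.testing.assert_allclose(scaled_dot_attention(q, k, v), expected, rtol=1e-6)
        np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-9)


def test_non_finite_attention_inputs_rejected():
    bad = np.full((2, 2), np.inf)
    with pytest.raises(ValueError):
        scaled_dot_attention(bad, bad, bad)


# ------------------------------------------------------------ cross-attention
def _cfg(n=8, h=2, blocks=3):
    return ModelConfig(n_features=n, n_heads=h, n_blocks=blocks)


def test_cross_attention_zero_output_projection_is_normalized_query():
    cfg = _cfg(n=6, h=1)
    params = init_extractor_params(cfg, np.random.default_rng(0))["gfe"][0]["layer1"]
    for i in range(1):
        params["Wq"][i].data = np.eye(6)
        params["Wk"][i].data = np.eye(6)
        params["Wv"][i].data = np.eye(6)
    params["Wo"].data = np.zeros((6, 6))
    rng = np.random.default_rng(2)
    q = rng.normal(size=(5, 6))
    kv = rng.normal(size=(7, 6))
    out = cross_attention(q, kv, params)
    np.testing.assert_allclose(out, ref_layer_norm(q, np.ones(6), np.zeros(6)), rtol=1e-9)


@pytest.mark.parametrize("h", [1, 2, 4])
def test_cross_attention_preserves_width_and_matches_oracle(h):
    cfg = _cfg(n=8, h=h)
    params = init_extractor_params(cfg, np.random.default_rng(h))["gfe"][0]["layer1"]
    rng = np.random.default_rng(3)
    q = rng.normal(size=(6, 8))
    kv = rng.normal(size=(6, 8))
    out = cross_attention(q, kv, params)
    assert out.shape == (6, 8)
    expected, _ = ref_cross_attention(q, kv, params)
    np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-9)


def test_gfe_block_is_the_two_layer_composition():
    cfg = _cfg()
    params = init_extractor_params(cfg, np.random.default_rng(5))
    rng = np.random.default_rng(6)
    seq = rng.normal(size=(7, 8))
    tdi = rng.normal(size=(7, 8))
    seq_hat, tdi_hat = gfe_block(seq, tdi, params["gfe"][0])
    tdi_ref = cross_attention(tdi, seq, params["gfe"][0]["layer1"])
    seq_ref = cross_attention(seq, tdi_ref, params["gfe"][0]["layer2"])
    np.testing.assert_allclose(tdi_hat, tdi_ref, rtol=1e-12)
    np.testing.assert_allclose(seq_hat, seq_ref, rtol=1e-12)
    assert seq_hat.shape == seq.shape and tdi_hat.shape == tdi.shape


# -------------------------------------------------------------------- local
def test_lfe_interior_positions_identical_for_constant_input():
    cfg = _cfg(n=4, h=1)
    block = init_extractor_params(cfg, np.random.default_rng(7))["lfe"][0]
    L = 30
    stacked = np.stack([np.tile([0.3, -1.0, 0.5, 2.0], (L, 1)),
                        np.tile([1.0, 0.0, -0.5, 0.25], (L, 1))])
    out = lfe_block(stacked, block)
    interior = out[5 : L - 5]  # > half of the largest kernel (11) from each end
    np.testing.assert_allclose(interior - interior[0], 0.0, atol=1e-9)


@pytest.mark.parametrize("L", [1, 2, 9, 17])
def test_lfe_same_padding_output_shape(L):
    cfg = _cfg(n=4, h=1)
    block = init_extractor_params(cfg, np.random.default_rng(8))["lfe"][0]
    out = lfe_block(np.random.default_rng(9).normal(size=(2, L, 4)), block)
    assert out.shape == (L, 4)


def test_lfe_matches_sliding_window_oracle():
    cfg = _cfg(n=4, h=1)
    block = init_extractor_params(cfg, np.random.default_rng(10))["lfe"][0]
    rng = np.random.default_rng(11)
    stacked = rng.normal(size=(2, 9, 4))
    expected = ref_lfe(stacked[0], stacked[1], block)
    np.testing.assert_allclose(lfe_block(stacked, block), expected, rtol=1e-6, atol=1e-9)


# ------------------------------------------------------------------ end to end
def test_extract_features_degenerate_length_one():
    cfg = _cfg(n=8, h=2)
    params = init_extractor_params(cfg, np.random.default_rng(12))
    pair = EmbeddingPair("p", np.random.default_rng(13).normal(size=(1, 8)),
                         np.random.default_rng(14).normal(size=(1, 8)))
    feats = extract_features(pair, params, cfg)
    assert feats.fused.shape == (1, 16)
    assert feats.pooled.shape == (16,)
    np.testing.assert_array_equal(feats.importance, np.zeros(1))


def test_fused_width_doubles_with_feature_width():
    for n in (4, 8):
        cfg = _cfg(n=n, h=2)
        params = init_extractor_params(cfg, np.random.default_rng(15))
        pair = EmbeddingPair("p", np.zeros((5, n)), np.zeros((5, n)))
        assert extract_features(pair, params, cfg).fused.shape == (5, 2 * n)


@pytest.mark.parametrize("h", [1, 2])
def test_full_forward_matches_straight_line_reference(h):
    cfg = _cfg(n=8, h=h)
    params = init_extractor_params(cfg, np.random.default_rng(16 + h))
    rng = np.random.default_rng(17)
    for L in (3, 12):
        seq = rng.normal(size=(L, 8))
        tdi = rng.normal(size=(L, 8))
        feats = extract_features(EmbeddingPair("p", seq, tdi), params, cfg)
        fused_ref, pooled_ref, w2_ref = ref_extract(seq, tdi, params, cfg)
        np.testing.assert_allclose(feats.fused, fused_ref, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(feats.pooled, pooled_ref, rtol=1e-5, atol=1e-8)


def test_forward_is_deterministic_bitwise():
    cfg = _cfg()
    params = init_extractor_params(cfg, np.random.default_rng(18))
    rng = np.random.default_rng(19)
    pair = EmbeddingPair("p", rng.normal(size=(9, 8)), rng.normal(size=(9, 8)))
    a = extract_features(pair, params, cfg)
    b = extract_features(pair, params, cfg)
    assert np.array_equal(a.fused, b.fused) and np.array_equal(a.pooled, b.pooled)


# ------------------------------------------------------------- importance map
def test_importance_uniform_attention_is_all_zeros():
    w = np.full((2, 5, 6), 1.0 / 6)
    np.testing.assert_array_equal(importance_from_weights(w), np.zeros(6))


def test_importance_dominant_key_scores_one():
    w = np.full((1, 4, 5), 0.1)
    w[:, :, 2] = 0.6
    scores = importance_from_weights(w)
    assert scores[2] == 1.0 and np.all(scores[np.arange(5) != 2] == 0.0)


def test_importance_tsv_export(tmp_path):
    from ecfuse.features import export_importance_tsv

    pair = EmbeddingPair("p1", np.zeros((3, 4)), np.zeros((3, 4)))
    path = tmp_path / "imp.tsv"
    export_importance_tsv(path, pair, "MKV", np.array([0.0, 0.5, 1.0]))
    lines = path.read_text().splitlines()
    assert lines[0] == "protein_id\tresidue_index\tamino_acid\tscore"
    assert lines[1].split("\t") == ["p1", "1", "M", "0.000000"]
    assert lines[3].split("\t") == ["p1", "3", "V", "1.000000"]
    with pytest.raises(ValueError):
        export_importance_tsv(path, pair, "MK", np.array([0.0, 0.5, 1.0]))


def test_importance_matches_recomputed_weights():
    cfg = _cfg()
    params = init_extractor_params(cfg, np.random.default_rng(20))
    rng = np.random.default_rng(21)
    seq = rng.normal(size=(10, 8))
    tdi = rng.normal(size=(10, 8))
    scores = attention_importance(EmbeddingPair("p", seq, tdi), params, cfg)
    _, _, w2 = ref_extract(seq, tdi, params, cfg)
    expected = w2.mean(axis=(0, 1))
    expected = (expected - expected.min()) / (expected.max() - expected.min())
    np.testing.assert_allclose(scores, expected, rtol=1e-6, atol=1e-9)
    assert scores.min() >= 0.0 and scores.max() <= 1.0
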