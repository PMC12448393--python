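"""Dual-pathway feature extraction: cross-attention fusion plus multi-kernel CNN.

Two per-residue embedding streams enter the network: a sequence stream and a
3Di (structure-token) stream, each an L x N matrix.  Two pathways process
them:

* **Global pathway** — a stack of blocks, each applying two cross-attention
  layers: first the 3Di stream attends to the sequence stream and is
  updated, then the sequence stream attends to the updated 3Di stream and is
  updated.  Each layer is multi-head scaled dot-product attention followed
  by a residual connection on the updated stream and layer normalization.
* **Local pathway** — a stack of blocks, each applying three parallel
  same-padded 1-D convolutions (kernel sizes 7, 9, 11) over a two-channel
  input, concatenating the three maps and mixing them back to width N with a
  per-position MLP.  Block 1 reads the raw (sequence, 3Di) pair; block i>1
  reads the pair (updated global sequence feature i-1, local output i-1).

The fused representation is the side-by-side concatenation of the final
global sequence features and the final local output (L x 2N), mean-pooled
over residues into a fixed-width protein vector for the prediction head and
for triplet distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import (
    Parameter,
    Tensor,
    concat,
    conv1d_same,
    layer_norm,
    softmax,
    uniform_init,
)
from .io import EmbeddingPair

ParamTree = dict


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    n_features is the embedding width N of both input streams; n_heads must
    divide it (per-head width N/h).  kernel_sizes are the parallel
    convolution widths of the local pathway and must be odd for symmetric
    same-padding.  use_global / use_local disable a pathway (identity
    pass-through / global-only fusion) for ablation studies.
    swap_layer1_roles flips which stream provides queries in the first
    cross-attention layer of every global block.
    """

    n_features: int = 16
    n_heads: int = 2
    n_blocks: int = 3
    kernel_sizes: tuple[int, ...] = (7, 9, 11)
    use_global: bool = True
    use_local: bool = True
    swap_layer1_roles: bool = False

    def __post_init__(self):
        if self.n_features % self.n_heads != 0:
            raise ValueError(
                f"n_features={self.n_features} must be divisible by n_heads={self.n_heads}"
            )
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError(f"kernel sizes must be odd, got {self.kernel_sizes}")
        if not (self.use_global or self.use_local):
            raise ValueError("cannot disable both the global and the local pathway")

    @property
    def head_width(self) -> int:
        return self.n_features // self.n_heads

    @property
    def fused_width(self) -> int:
        if not self.use_local:
            return self.n_features
        if not self.use_global:
            return 2 * self.n_features
        return 2 * self.n_features

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_heads": self.n_heads,
            "n_blocks": self.n_blocks,
            "kernel_sizes": list(self.kernel_sizes),
            "use_global": self.use_global,
            "use_local": self.use_local,
            "swap_layer1_roles": self.swap_layer1_roles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["kernel_sizes"] = tuple(d.get("kernel_sizes", (7, 9, 11)))
        return cls(**d)


# --------------------------------------------------------------------- params
def _init_attention_layer(rng: np.random.Generator, cfg: ModelConfig) -> ParamTree:
    n, hw = cfg.n_features, cfg.head_width
    return {
        "Wq": [uniform_init(rng, (n, hw), n) for _ in range(cfg.n_heads)],
        "Wk": [uniform_init(rng, (n, hw), n) for _ in range(cfg.n_heads)],
        "Wv": [uniform_init(rng, (n, hw), n) for _ in range(cfg.n_heads)],
        "Wo": uniform_init(rng, (n, n), n),
        "bo": Parameter(np.zeros(n)),
        "ln_gamma": Parameter(np.ones(n)),
        "ln_beta": Parameter(np.zeros(n)),
    }


def _init_lfe_block(rng: np.random.Generator, cfg: ModelConfig) -> ParamTree:
    n = cfg.n_features
    c_in = 2 * n
    convs = {}
    for k in cfg.kernel_sizes:
        convs[k] = {
            "w": uniform_init(rng, (k, c_in, n), k * c_in),
            "b": Parameter(np.zeros(n)),
        }
    m = len(cfg.kernel_sizes) * n
    return {
        "convs": convs,
        "mlp": {
            "W1": uniform_init(rng, (m, m), m),
            "b1": Parameter(np.zeros(m)),
            "W2": uniform_init(rng, (m, n), m),
            "b2": Parameter(np.zeros(n)),
        },
    }


def init_extractor_params(cfg: ModelConfig, rng: np.random.Generator) -> ParamTree:
    """Seeded variance-scaled-uniform init (zero biases) for both pathways."""
    params: ParamTree = {"gfe": [], "lfe": []}
    if cfg.use_global:
        params["gfe"] = [
            {"layer1": _init_attention_layer(rng, cfg), "layer2": _init_attention_layer(rng, cfg)}
            for _ in range(cfg.n_blocks)
        ]
    if cfg.use_local:
        params["lfe"] = [_init_lfe_block(rng, cfg) for _ in range(cfg.n_blocks)]
    return params


def iter_parameters(tree) -> list[Parameter]:
    """Flatten a parameter tree into a deterministic list of leaves."""
    out: list[Parameter] = []
    if isinstance(tree, Parameter):
        out.append(tree)
    elif isinstance(tree, dict):
        for key in tree:  # insertion order is deterministic
            out.extend(iter_parameters(tree[key]))
    elif isinstance(tree, (list, tuple)):
        for item in tree:
            out.extend(iter_parameters(item))
    return out


# ----------------------------------------------------------------- operations
def scaled_dot_attention_t(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """Softmax(Q K^T / sqrt(d_k)) V; returns (output, attention weights)."""
    d_k = q.shape[-1]
    logits = (q @ k.T) * (1.0 / np.sqrt(d_k))
    weights = softmax(logits, axis=-1)
    return weights @ v, weights


def scaled_dot_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Array-in/array-out scaled dot-product attention (single head)."""
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    if not all(np.isfinite(a).all() for a in (q, k, v)):
        raise ValueError("non-finite attention inputs")
    out, _ = scaled_dot_attention_t(Tensor(q), Tensor(k), Tensor(v))
    return out.data


def cross_attention_t(
    query: Tensor, kv: Tensor, params: ParamTree
) -> tuple[Tensor, np.ndarray]:
    """Multi-head cross-attention updating the query stream.

    Heads use separate projection matrices, are concatenated to width N,
    linearly mixed, residual-added to the query stream and layer-normalized.
    Returns (updated stream L x N, attention weights (h, L_q, L_k)).
    """
    heads = []
    weights = []
    for wq, wk, wv in zip(params["Wq"], params["Wk"], params["Wv"]):
        out, w = scaled_dot_attention_t(query @ wq, kv @ wk, kv @ wv)
        heads.append(out)
        weights.append(w.data)
    mixed = concat(heads, axis=-1) @ params["Wo"] + params["bo"]
    updated = layer_norm(query + mixed, params["ln_gamma"], params["ln_beta"])
    return updated, np.stack(weights)


def cross_attention(query: np.ndarray, kv: np.ndarray, params: ParamTree) -> np.ndarray:
    out, _ = cross_attention_t(Tensor(query), Tensor(kv), params)
    return out.data


def gfe_block_t(
    seq: Tensor, tdi: Tensor, block: ParamTree, swap_layer1_roles: bool = False
) -> tuple[Tensor, Tensor, np.ndarray]:
    """One global block: update 3Di from sequence, then sequence from updated 3Di.

    Returns (seq_hat, tdi_hat, layer-2 attention weights).  With
    swap_layer1_roles the first layer's queries come from the sequence
    stream (the literal equation-subscript reading) while the residual still
    updates the 3Di stream.
    """
    if swap_layer1_roles:
        heads, weights = [], []
        p = block["layer1"]
        for wq, wk, wv in zip(p["Wq"], p["Wk"], p["Wv"]):
            out, w = scaled_dot_attention_t(seq @ wq, tdi @ wk, tdi @ wv)
            heads.append(out)
            weights.append(w.data)
        mixed = concat(heads, axis=-1) @ p["Wo"] + p["bo"]
        tdi_hat = layer_norm(tdi + mixed, p["ln_gamma"], p["ln_beta"])
    else:
        tdi_hat, _ = cross_attention_t(tdi, seq, block["layer1"])
    seq_hat, w2 = cross_attention_t(seq, tdi_hat, block["layer2"])
    return seq_hat, tdi_hat, w2


def gfe_block(
    seq: np.ndarray, tdi: np.ndarray, block: ParamTree, swap_layer1_roles: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    s, t, _ = gfe_block_t(Tensor(seq), Tensor(tdi), block, swap_layer1_roles)
    return s.data, t.data


def lfe_block_t(chan_a: Tensor, chan_b: Tensor, block: ParamTree) -> Tensor:
    """One local block on a two-channel (each L x N) input.

    The channel pair is flattened to 2N feature channels per position; each
    kernel maps 2N -> N channels with same-padding; the concatenated 3N map
    goes through a one-hidden-layer per-position MLP (width 3N, relu) back
    to width N.
    """
    x = concat([chan_a, chan_b], axis=-1)  # (L, 2N)
    branches = [
        conv1d_same(x, block["convs"][k]["w"], block["convs"][k]["b"])
        for k in block["convs"]
    ]
    cat = concat(branches, axis=-1)  # (L, 3N)
    mlp = block["mlp"]
    hidden = (cat @ mlp["W1"] + mlp["b1"]).relu()
    return hidden @ mlp["W2"] + mlp["b2"]


def lfe_block(stacked: np.ndarray, block: ParamTree) -> np.ndarray:
    """Array interface: ``stacked`` has shape (2, L, N)."""
    stacked = np.asarray(stacked, dtype=np.float64)
    if stacked.ndim != 3 or stacked.shape[0] != 2:
        raise ValueError(f"expected a (2, L, N) channel stack, got {stacked.shape}")
    if stacked.shape[1] < 1:
        raise ValueError("L must be >= 1")
    return lfe_block_t(Tensor(stacked[0]), Tensor(stacked[1]), block).data


@dataclass
class FusedFeatures:
    """Output of the extraction network for one protein."""

    protein_id: str
    fused: np.ndarray  # (L, fused_width)
    pooled: np.ndarray  # (fused_width,)
    importance: np.ndarray | None = None  # per-residue attention score in [0, 1]


def forward_features_t(
    seq: Tensor, tdi: Tensor, params: ParamTree, cfg: ModelConfig
) -> tuple[Tensor, Tensor, np.ndarray | None]:
    """Full extraction forward pass in tensor mode.

    Returns (fused L x fused_width, pooled vector, attention weights of the
    final global block's second layer, or None when the global pathway is
    disabled).
    """
    seq_hats: list[Tensor] = []
    last_w2: np.ndarray | None = None
    cur_seq, cur_tdi = seq, tdi
    for i in range(cfg.n_blocks):
        if cfg.use_global:
            cur_seq, cur_tdi, last_w2 = gfe_block_t(
                cur_seq, cur_tdi, params["gfe"][i], cfg.swap_layer1_roles
            )
        seq_hats.append(cur_seq)

    local_out: Tensor | None = None
    if cfg.use_local:
        chan_a, chan_b = seq, tdi  # first block reads the raw pair
        for i in range(cfg.n_blocks):
            if i > 0:
                chan_a, chan_b = seq_hats[i - 1], local_out
            local_out = lfe_block_t(chan_a, chan_b, params["lfe"][i])

    if cfg.use_local:
        fused = concat([seq_hats[-1], local_out], axis=-1)
    else:
        fused = seq_hats[-1]
    pooled = fused.mean(axis=0)
    return fused, pooled, last_w2


def importance_from_weights(weights: np.ndarray) -> np.ndarray:
    """Per-residue importance from an (h, L_q, L_k) attention weight tensor.

    Mean over heads and query positions, then min-max normalized over key
    positions; when all scores tie (including L = 1) the normalization is
    degenerate and the scores are defined as all zeros.
    """
    scores = weights.mean(axis=(0, 1))
    lo, hi = scores.min(), scores.max()
    if hi - lo < 1e-12:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def extract_features(pair: EmbeddingPair, params: ParamTree, cfg: ModelConfig) -> FusedFeatures:
    """Run the dual-pathway network on one protein (array in / array out)."""
    if pair.width != cfg.n_features:
        raise ValueError(
            f"{pair.protein_id}: embedding width {pair.width} != model width {cfg.n_features}"
        )
    fused, pooled, w2 = forward_features_t(
        Tensor(pair.seq_embedding), Tensor(pair.tdi_embedding), params, cfg
    )
    imp = importance_from_weights(w2) if w2 is not None else None
    return FusedFeatures(pair.protein_id, fused.data, pooled.data, imp)


def attention_importance(pair: EmbeddingPair, params: ParamTree, cfg: ModelConfig) -> np.ndarray:
    """Per-residue attention importance in [0, 1] (see importance_from_weights)."""
    if not cfg.use_global:
        raise ValueError("attention importance requires the global pathway")
    feats = extract_features(pair, params, cfg)
    assert feats.importance is not None
    return feats.importance


def export_importance_tsv(path, pair: EmbeddingPair, sequence: str, scores: np.ndarray) -> None:
    """Write ``protein_id, residue_index (1-based), amino_acid, score`` rows."""
    if len(sequence) != len(scores):
        raise ValueError("sequence and score lengths differ")
    with open(path, "w") as fh:
        fh.write("protein_id\tresidue_index\tamino_acid\tscore\n")
        for i, (aa, s) in enumerate(zip(sequence, scores), start=1):
            fh.write(f"{pair.protein_id}\t{i}\t{aa}\t{s:.6f}\n")
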