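"""Autoregressive four-level EC prediction head and prefix-consistent decoding.

Four MLPs predict the four EC levels in order over the prefix label spaces.
The level-1 MLP reads the pooled fused feature vector; each later MLP reads
that vector concatenated with the previous level's prediction vector —
the ground-truth multi-hot during training (teacher forcing), the previous
sigmoid outputs at inference.  Feeding the whole previous vector (rather
than one decoded digit) lets multi-EC enzymes keep several active parents.

Decoding thresholds the level-4 sigmoids at tau and keeps a label only when
its entire ancestor chain also clears tau (confidence = the chain minimum).
When nothing clears the threshold a single EC is produced by a greedy
root-to-leaf walk restricted to the observed child-of map, so every protein
receives at least one prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Parameter, Tensor, concat, uniform_init
from .ontology import LEVELS, LabelSpaces

ParamTree = dict


def init_head_params(
    fused_width: int,
    spaces: LabelSpaces,
    rng: np.random.Generator,
    autoregressive: bool = True,
) -> ParamTree:
    """Four two-layer MLPs (hidden width = input width, relu, sigmoid output).

    With ``autoregressive=False`` (head ablation) every MLP reads only the
    pooled features — four independent per-level classifiers.
    """
    mlps = []
    for j in range(LEVELS):
        width_in = fused_width
        if autoregressive and j > 0:
            width_in += len(spaces.vocab[j - 1])
        width_out = len(spaces.vocab[j])
        mlps.append(
            {
                "W1": uniform_init(rng, (width_in, width_in), width_in),
                "b1": Parameter(np.zeros(width_in)),
                "W2": uniform_init(rng, (width_in, width_out), width_in),
                "b2": Parameter(np.zeros(width_out)),
            }
        )
    return {"mlps": mlps, "autoregressive": autoregressive}


def _mlp_t(x: Tensor, mlp: ParamTree) -> Tensor:
    hidden = (x @ mlp["W1"] + mlp["b1"]).relu()
    return (hidden @ mlp["W2"] + mlp["b2"]).sigmoid()


def autoregressive_forward_t(
    pooled: Tensor,
    params: ParamTree,
    prev_override: list[np.ndarray] | None = None,
) -> list[Tensor]:
    """Per-level sigmoid probability tensors for a (B, fused_width) batch.

    ``prev_override`` supplies the previous-level vectors (teacher forcing:
    the ground-truth multi-hots); when None the head consumes its own
    predicted probabilities (inference).  Entry ``prev_override[j]`` feeds
    MLP_{j+1}; the list has LEVELS-1 entries.
    """
    outputs: list[Tensor] = []
    autoregressive = params["autoregressive"]
    for j, mlp in enumerate(params["mlps"]):
        if j == 0 or not autoregressive:
            x = pooled
        else:
            if prev_override is not None:
                prev: Tensor = Tensor(prev_override[j - 1])
            else:
                prev = outputs[j - 1]
            x = concat([prev, pooled], axis=-1)
        outputs.append(_mlp_t(x, mlp))
    return outputs


def autoregressive_forward(
    pooled: np.ndarray,
    params: ParamTree,
    prev_override: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Array interface; accepts a single vector or a (B, fused_width) batch."""
    pooled = np.asarray(pooled, dtype=np.float64)
    single = pooled.ndim == 1
    if single:
        pooled = pooled[None, :]
        if prev_override is not None:
            prev_override = [np.asarray(p)[None, :] for p in prev_override]
    expected = params["mlps"][0]["W1"].shape[0]
    if pooled.shape[1] != expected:
        raise ValueError(f"pooled width {pooled.shape[1]} != head input width {expected}")
    outs = [t.data for t in autoregressive_forward_t(Tensor(pooled), params, prev_override)]
    if single:
        outs = [o[0] for o in outs]
    return outs


@dataclass
class PredictionResult:
    """Per-level probabilities plus the decoded EC set with confidences."""

    protein_id: str
    probabilities: list[np.ndarray]
    predictions: list[tuple[str, float]]  # (EC string, confidence), confidence-sorted

    @property
    def ec_set(self) -> set[str]:
        return {ec for ec, _ in self.predictions}


def _chain_of(label: str, spaces: LabelSpaces) -> list[str]:
    """Ancestor chain of a level-4 label, root first."""
    chain = [label]
    for k in range(LEVELS - 1, 0, -1):
        chain.append(spaces.parent[k][chain[-1]])
    return chain[::-1]


def decode_predictions(
    probabilities: list[np.ndarray],
    spaces: LabelSpaces,
    threshold: float = 0.5,
) -> list[tuple[str, float]]:
    """Threshold-with-fallback decoding of per-level probabilities.

    Returns (EC string, confidence) pairs, sorted by decreasing confidence
    then label.  Every returned EC is prefix-consistent by construction, and
    the greedy fallback guarantees a non-empty result.
    """
    if len(probabilities) != LEVELS:
        raise ValueError("expected four probability vectors")
    probs = [np.asarray(p, dtype=np.float64) for p in probabilities]
    for k, p in enumerate(probs):
        if p.shape != (len(spaces.vocab[k]),):
            raise ValueError(
                f"level-{k + 1} probability length {p.shape} != vocabulary size "
                f"{len(spaces.vocab[k])}"
            )
    results: list[tuple[str, float]] = []
    for i, label in enumerate(spaces.vocab[LEVELS - 1]):
        chain = _chain_of(label, spaces)
        chain_probs = [probs[k][spaces.index[k][c]] for k, c in enumerate(chain)]
        if all(p >= threshold for p in chain_probs):
            results.append((label, float(min(chain_probs))))
    if not results:
        # greedy root-to-leaf argmax restricted to the child-of map
        label = spaces.vocab[0][int(np.argmax(probs[0]))]
        conf = float(probs[0].max())
        for k in range(1, LEVELS):
            children = [lab for lab in spaces.vocab[k] if spaces.parent[k][lab] == label]
            scores = [probs[k][spaces.index[k][c]] for c in children]
            best = int(np.argmax(scores))
            label = children[best]
            conf = min(conf, float(scores[best]))
        results.append((label, conf))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results


def write_predictions_tsv(path, results: list[PredictionResult]) -> None:
    """``protein_id<TAB>EC/confidence;EC/confidence;...`` (multi-EC style)."""
    with open(path, "w") as fh:
        for res in results:
            cell = ";".join(f"{ec}/{conf:.4f}" for ec, conf in res.predictions)
            fh.write(f"{res.protein_id}\t{cell}\n")


def read_predictions_tsv(path) -> dict[str, set[str]]:
    """Read back a predictions TSV into id -> EC-string set (confidences dropped)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, cell = line.split("\t")
            out[pid] = {tok.split("/")[0] for tok in cell.split(";") if tok}
    return out
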