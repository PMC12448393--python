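"""Losses, triplet mining and the two-phase training loop.

Phase 1 trains only the feature-extraction network with a triplet loss on
mean-pooled fused features (Euclidean distance): an anchor is pulled toward
a positive sharing at least one full EC number and pushed from a negative
sharing none, with a fixed margin.  Phase 2 freezes the extractor, caches
every protein's pooled features once (which is what allows very large
batches), and trains the four prediction MLPs with a summed multi-level
binary cross-entropy under teacher forcing.

The combined objective is ``lambda1 * L_triplet + lambda2 * L_BCE``; phase 1
uses (lambda1, lambda2) = (1, 0) and phase 2 uses (0, 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Adam, Tensor
from .features import (
    ModelConfig,
    forward_features_t,
    init_extractor_params,
    iter_parameters,
)
from .io import Dataset
from .ontology import LabelSpaces, TargetEncoding, encode_targets
from .prediction import autoregressive_forward_t, init_head_params

logger = logging.getLogger(__name__)

ParamTree = dict
BCE_EPS = 1e-7


@dataclass
class PhaseSchedule:
    epochs: int
    batch_size: int
    lr: float
    cosine_annealing: bool = False

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("phase schedule values must be positive")


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults follow the published recipe.

    Phase 1: batch 40, 1000 epochs, constant lr 5e-4.  Phase 2: batch
    50 000, 150 epochs, lr 1e-3 with cosine annealing.  Adam moments
    (0.9, 0.999).  ``triplets_per_epoch`` controls how many triplets are
    mined each phase-1 epoch (one batch's worth by default).
    """

    margin: float = 1.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    scheduled_sampling: float = 0.0  # prob. of self-predicted prev inputs in phase 2
    phase1: PhaseSchedule = field(default_factory=lambda: PhaseSchedule(1000, 40, 5e-4))
    phase2: PhaseSchedule = field(
        default_factory=lambda: PhaseSchedule(150, 50_000, 1e-3, cosine_annealing=True)
    )
    betas: tuple[float, float] = (0.9, 0.999)
    triplets_per_epoch: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for key in ("phase1", "phase2"):
            if key in d and isinstance(d[key], dict):
                d[key] = PhaseSchedule(**d[key])
        if "betas" in d:
            d["betas"] = tuple(d["betas"])
        return cls(**d)


# ------------------------------------------------------------------- losses
def euclidean_t(x: Tensor, y: Tensor) -> Tensor:
    return (((x - y) ** 2.0).sum() + 1e-12) ** 0.5


def l2_normalize_t(x: Tensor) -> Tensor:
    return x * (((x ** 2.0).sum() + 1e-12) ** -0.5)


def triplet_loss(
    anchors: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
    margin: float = 1.0,
) -> float:
    """Sum over triplets of max(0, d(a,p) - d(a,n) + margin), Euclidean d."""
    a = np.atleast_2d(np.asarray(anchors, dtype=np.float64))
    p = np.atleast_2d(np.asarray(positives, dtype=np.float64))
    n = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if not (a.shape == p.shape == n.shape):
        raise ValueError(f"triplet shape mismatch: {a.shape}, {p.shape}, {n.shape}")
    d_ap = np.sqrt(((a - p) ** 2).sum(axis=1))
    d_an = np.sqrt(((a - n) ** 2).sum(axis=1))
    return float(np.maximum(0.0, d_ap - d_an + margin).sum())


def triplet_loss_t(
    anchors: list[Tensor], positives: list[Tensor], negatives: list[Tensor], margin: float
) -> Tensor:
    terms = []
    for a, p, n in zip(anchors, positives, negatives):
        terms.append((euclidean_t(a, p) - euclidean_t(a, n) + margin).relu())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def bce_multilevel_loss(
    pred_levels: list[np.ndarray], target_levels: list[np.ndarray], eps: float = BCE_EPS
) -> float:
    """Summed binary cross-entropy over all levels and vocabulary entries."""
    if len(pred_levels) != len(target_levels):
        raise ValueError("level count mismatch")
    total = 0.0
    for p, y in zip(pred_levels, target_levels):
        p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
        y = np.asarray(y, dtype=np.float64)
        if p.shape != y.shape:
            raise ValueError(f"prediction/target shape mismatch: {p.shape} vs {y.shape}")
        total += float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())
    return total


def bce_multilevel_loss_t(
    pred_levels: list[Tensor], target_levels: list[np.ndarray], eps: float = BCE_EPS
) -> Tensor:
    total: Tensor | None = None
    for p, y in zip(pred_levels, target_levels):
        y = np.asarray(y, dtype=np.float64)
        pc = p.clip(eps, 1.0 - eps)
        term = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()).sum()
        total = term if total is None else total + term
    assert total is not None
    return total


def total_loss(l_triplet: float, l_bce: float, lambda1: float, lambda2: float) -> float:
    """Weighted combination of the two objectives."""
    return lambda1 * l_triplet + lambda2 * l_bce


# ------------------------------------------------------------- triplet mining
def sample_triplets(
    ec_sets: list[set[str]], count: int, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Mine (anchor, positive, negative) index triples.

    Anchor and positive share at least one full EC number; the negative
    shares none with the anchor.  Negatives are hardness-biased: with
    probability 1/2 each, the negative is drawn from the deepest non-empty
    EC-prefix stratum around the anchor (same sub-subclass first, then same
    subclass, same class, finally any disjoint enzyme) — uniformly random
    negatives are almost always trivially separated and contribute no
    hinge gradient.  Anchors whose every EC class has a single member are
    skipped (logged once).  Raises when some anchor has no valid negative.
    """
    n = len(ec_sets)
    members: dict[str, list[int]] = {}
    for i, ecs in enumerate(ec_sets):
        for ec in ecs:
            members.setdefault(ec, []).append(i)
    has_positive = [any(len(members[ec]) > 1 for ec in ec_sets[i]) for i in range(n)]
    eligible = [i for i in range(n) if has_positive[i]]
    skipped = n - len(eligible)
    if skipped:
        logger.info("sample_triplets: %d proteins have no positive partner; skipped", skipped)
    if not eligible:
        raise ValueError("no EC class has two members; cannot mine positives")

    def prefixes(ecs: set[str], depth: int) -> set[str]:
        return {".".join(ec.split(".")[:depth]) for ec in ecs}

    triples: list[tuple[int, int, int]] = []
    for _ in range(count):
        a = int(rng.choice(eligible))
        shared = [ec for ec in sorted(ec_sets[a]) if len(members[ec]) > 1]
        ec = shared[int(rng.integers(len(shared)))]
        pool = [j for j in members[ec] if j != a]
        p = int(pool[int(rng.integers(len(pool)))])
        negatives = [j for j in range(n) if not (ec_sets[j] & ec_sets[a])]
        if not negatives:
            raise ValueError(f"no valid negative for anchor {a}")
        # hardness-biased strata: deepest shared prefix first
        chosen_pool = negatives
        for depth in (3, 2, 1):
            anchor_pref = prefixes(ec_sets[a], depth)
            stratum = [j for j in negatives if prefixes(ec_sets[j], depth) & anchor_pref]
            if stratum and rng.random() < 0.5:
                chosen_pool = stratum
                break
        neg = int(chosen_pool[int(rng.integers(len(chosen_pool)))])
        triples.append((a, p, neg))
    return triples


# ------------------------------------------------------------ feature cache
def compute_pooled_features(
    dataset: Dataset, extractor_params: ParamTree, model_cfg: ModelConfig
) -> np.ndarray:
    """Pooled fused feature matrix (n_proteins, fused_width), detached."""
    rows = []
    for pair, _ in dataset.records:
        _, pooled, _ = forward_features_t(
            Tensor(pair.seq_embedding), Tensor(pair.tdi_embedding), extractor_params, model_cfg
        )
        rows.append(pooled.data)
    return np.stack(rows)


def encode_dataset_targets(dataset: Dataset) -> list[TargetEncoding]:
    return [encode_targets(ecs, dataset.label_spaces) for _, ecs in dataset.records]


# ------------------------------------------------------------- training loops
def _check_finite(loss: float, phase: str, epoch: int) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"{phase} diverged at epoch {epoch}: loss={loss!r}; "
            "lower the learning rate or check the input scale"
        )


def train_phase1(
    dataset: Dataset,
    extractor_params: ParamTree,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Contrastive pre-training of the extractor; returns a per-epoch trace.

    Only extractor parameters receive gradients; the prediction head is
    untouched (the freeze contract is exact, not approximate).  The triplet
    distance is Euclidean on L2-normalized pooled features, the standard
    device that keeps a fixed margin (default 1.0) meaningful regardless of
    the feature scale; without it the hinge can be vacuously satisfied at
    initialization and the phase provides no gradient.
    """
    ec_sets = [set(str(e) for e in ecs) for _, ecs in dataset.records]
    params = iter_parameters(extractor_params)
    opt = Adam(params, lr=train_cfg.phase1.lr, betas=train_cfg.betas)
    trace: list[dict] = []
    sched = train_cfg.phase1
    for epoch in range(sched.epochs):
        triples = sample_triplets(ec_sets, train_cfg.triplets_per_epoch, rng)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(triples), sched.batch_size):
            batch = triples[start : start + sched.batch_size]
            needed = sorted({i for tri in batch for i in tri})
            pooled: dict[int, Tensor] = {}
            for i in needed:
                pair = dataset.records[i][0]
                _, pool_t, _ = forward_features_t(
                    Tensor(pair.seq_embedding),
                    Tensor(pair.tdi_embedding),
                    extractor_params,
                    model_cfg,
                )
                if not np.isfinite(pool_t.data).all():
                    raise RuntimeError(
                        f"phase 1 diverged at epoch {epoch}: non-finite features for "
                        f"{pair.protein_id}; lower the learning rate or check the input scale"
                    )
                pooled[i] = l2_normalize_t(pool_t)
            loss = triplet_loss_t(
                [pooled[a] for a, _, _ in batch],
                [pooled[p] for _, p, _ in batch],
                [pooled[n] for _, _, n in batch],
                train_cfg.margin,
            )
            _check_finite(loss.item(), "phase 1", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() / len(batch)
            n_batches += 1
        trace.append(
            {"phase": 1, "epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "lr": opt.lr}
        )
    return trace


def train_phase2(
    dataset: Dataset,
    extractor_params: ParamTree,
    head_params: ParamTree,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
    pooled_cache: np.ndarray | None = None,
) -> list[dict]:
    """Head training on frozen pooled features with teacher forcing.

    ``pooled_cache`` may supply precomputed pooled features; when absent
    they are computed once here.  Extractor parameters are never updated.
    With probability ``train_cfg.scheduled_sampling`` (default 0: pure
    teacher forcing) a batch conditions each level on the head's own
    previous-level predictions instead of the ground-truth multi-hots.
    """
    if pooled_cache is None:
        pooled_cache = compute_pooled_features(dataset, extractor_params, model_cfg)
    targets = encode_dataset_targets(dataset)
    n = len(dataset.records)
    target_mats = [
        np.stack([targets[i].levels[k] for i in range(n)]) for k in range(4)
    ]
    params = iter_parameters(head_params["mlps"])
    sched = train_cfg.phase2
    n_batches_per_epoch = int(np.ceil(n / min(sched.batch_size, n)))
    total_steps = sched.epochs * n_batches_per_epoch
    opt = Adam(
        params,
        lr=sched.lr,
        betas=train_cfg.betas,
        cosine_t_max=total_steps if sched.cosine_annealing else None,
    )
    trace: list[dict] = []
    for epoch in range(sched.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, sched.batch_size):
            idx = order[start : start + sched.batch_size]
            pooled_t = Tensor(pooled_cache[idx])
            if train_cfg.scheduled_sampling > 0 and rng.random() < train_cfg.scheduled_sampling:
                free = autoregressive_forward_t(Tensor(pooled_cache[idx]), head_params)
                teacher = [t.data.copy() for t in free[:3]]
            else:
                teacher = [target_mats[k][idx] for k in range(3)]
            preds = autoregressive_forward_t(pooled_t, head_params, prev_override=teacher)
            loss = bce_multilevel_loss_t(preds, [target_mats[k][idx] for k in range(4)])
            _check_finite(loss.item(), "phase 2", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
        trace.append({"phase": 2, "epoch": epoch, "loss": epoch_loss / n, "lr": opt.lr})
    return trace


# --------------------------------------------------------------- checkpoints
def _named_arrays(tree, prefix: str, out: dict) -> None:
    from ._autodiff import Parameter

    if isinstance(tree, Parameter):
        out[prefix] = tree.data
    elif isinstance(tree, dict):
        for key, val in tree.items():
            if isinstance(val, (dict, list, tuple)) or hasattr(val, "data"):
                _named_arrays(val, f"{prefix}.{key}" if prefix else str(key), out)
    elif isinstance(tree, (list, tuple)):
        for i, val in enumerate(tree):
            _named_arrays(val, f"{prefix}.{i}", out)


def _assign_named_arrays(tree, prefix: str, arrays: dict) -> None:
    from ._autodiff import Parameter

    if isinstance(tree, Parameter):
        tree.data = np.asarray(arrays[prefix], dtype=np.float64)
    elif isinstance(tree, dict):
        for key, val in tree.items():
            if isinstance(val, (dict, list, tuple)) or hasattr(val, "data"):
                _assign_named_arrays(val, f"{prefix}.{key}" if prefix else str(key), arrays)
    elif isinstance(tree, (list, tuple)):
        for i, val in enumerate(tree):
            _assign_named_arrays(val, f"{prefix}.{i}", arrays)


CHECKPOINT_VERSION = 1


def save_checkpoint(
    path,
    model_cfg: ModelConfig,
    extractor_params: ParamTree,
    head_params: ParamTree | None,
    spaces: LabelSpaces,
    train_cfg: TrainConfig | None = None,
) -> None:
    """Single-file checkpoint: parameter arrays plus an embedded JSON config."""
    arrays: dict[str, np.ndarray] = {}
    _named_arrays(extractor_params, "ext", arrays)
    if head_params is not None:
        _named_arrays(head_params["mlps"], "head", arrays)
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": model_cfg.to_dict(),
        "label_spaces": spaces.to_dict(),
        "autoregressive": bool(head_params["autoregressive"]) if head_params else None,
        "train_config": train_cfg.to_dict() if train_cfg else None,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[ModelConfig, ParamTree, ParamTree | None, LabelSpaces]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    cfg = ModelConfig.from_dict(meta["model_config"])
    spaces = LabelSpaces.from_dict(meta["label_spaces"])
    rng = np.random.default_rng(0)  # placeholder values, overwritten below
    extractor = init_extractor_params(cfg, rng)
    _assign_named_arrays(extractor, "ext", arrays)
    head = None
    if meta["autoregressive"] is not None:
        head = init_head_params(cfg.fused_width, spaces, rng, meta["autoregressive"])
        _assign_named_arrays(head["mlps"], "head", arrays)
    return cfg, extractor, head, spaces


def write_trace_jsonl(path, trace: list[dict]) -> None:
    with open(path, "w") as fh:
        for row in trace:
            fh.write(json.dumps(row) + "\n")
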