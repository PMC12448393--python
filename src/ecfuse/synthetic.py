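"""Synthetic embedding-pair benchmark generator.

Real inputs to the classifier are per-residue embeddings of the amino-acid
sequence and of its 3Di (structure-token) string, labelled with one or more
four-level EC numbers.  This module generates datasets with the same
statistical skeleton so the whole pipeline is testable without any
pre-trained embedder or database download:

* a four-level label tree with configurable branching;
* one latent class prototype per tree node, built hierarchically — each
  node adds a scaled random increment to its parent's prototype, so sibling
  leaves differ only by their level-4 increment;
* a 3Di prototype channel that mixes a fixed linear transform of the
  sequence prototype with fresh class-specific directions, controlled by
  the correlation ``rho`` (at rho = 1 the 3Di channel carries no signal the
  sequence channel lacks; below 1 part of the class signal lives only in
  the 3Di modality);
* a planted "functional-site" window per protein: a contiguous stretch of
  residues receiving an extra leaf-specific local signal, giving the local
  convolution pathway a learnable target and residue-importance scores a
  ground truth;
* optional multi-label proteins whose second EC shares the level-3 prefix
  (mirroring real multi-EC enzymes whose serial numbers differ within one
  sub-subclass); their embeddings mix the two leaves' level-4 signals so
  the second label is learnable rather than pure label noise;
* a parent-dependence knob: with strength 1 the level-4 increment
  directions are shared across level-3 parents, so leaf identity is the
  conjunction "parent x shared child direction" — exactly the regime in
  which conditioning level-4 prediction on the level-3 prediction helps;
* i.i.d. Gaussian residue noise of scale ``sigma`` on every embedding row.

All randomness flows through one seeded generator; the same seed yields a
bit-identical dataset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import Dataset, EmbeddingPair, write_embeddings, write_fasta, write_labels_tsv
from .ontology import ECNumber, build_label_spaces, parse_ec

#: the 20-letter 3Di structural alphabet (same letter set as amino acids)
TDI_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Generator parameters; the defaults are the package's reference fixture.

    branching fixes the label tree (leaf count = product); separation is the
    base inter-class distance scale and level_scales its per-level decay, so
    deeper distinctions are finer — as in the real EC hierarchy where
    serial numbers within a sub-subclass are much harder to tell apart than
    top-level classes.  noise_sigma is the per-residue Gaussian noise sd,
    rho the sequence<->3Di prototype correlation, motif_strength the local
    signal magnitude in units of separation.
    """

    branching: tuple[int, int, int, int] = (3, 2, 2, 2)
    proteins_per_leaf: int = 25
    length_range: tuple[int, int] = (24, 40)
    n_features: int = 16
    separation: float = 3.0
    noise_sigma: float = 0.5
    rho: float = 0.75
    motif_len: int = 9
    motif_strength: float = 1.5
    multi_label_p: float = 0.1
    parent_dependence: float = 0.5
    level_scales: tuple[float, float, float, float] = (1.0, 0.7, 0.5, 0.4)
    seed: int = 0

    def __post_init__(self):
        if any(b < 1 for b in self.branching):
            raise ValueError("branching factors must be >= 1")
        if self.proteins_per_leaf < 1 or self.n_features < 1:
            raise ValueError("proteins_per_leaf and n_features must be positive")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length range")
        if self.motif_len > self.length_range[0]:
            raise ValueError("length range lower bound is below the motif length")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.multi_label_p < 1.0:
            raise ValueError("multi_label_p must be in [0, 1)")
        if not 0.0 <= self.parent_dependence <= 1.0:
            raise ValueError("parent_dependence must be in [0, 1]")
        if self.noise_sigma < 0 or self.separation < 0 or self.motif_strength < 0:
            raise ValueError("scales must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("branching", "length_range", "level_scales"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SynthDataset:
    """A generated dataset plus its generating ground truth."""

    dataset: Dataset
    motif_spans: dict[str, tuple[int, int]]  # 1-based inclusive (start, end)
    leaf_of: dict[str, str]  # protein id -> primary leaf EC string
    seq_prototypes: dict[str, np.ndarray]  # leaf EC -> global sequence prototype
    tdi_prototypes: dict[str, np.ndarray]
    sequences: dict[str, str]
    tdi_strings: dict[str, str]
    config: SynthConfig


def generate_label_tree(config: SynthConfig) -> list[ECNumber]:
    """Enumerate the leaf EC numbers of a synthetic four-level tree.

    Digit values are assigned deterministically (1..branching at each
    level), so leaf count equals the product of the branching factors.
    """
    b1, b2, b3, b4 = config.branching
    leaves = [
        ECNumber(i, j, k, l)
        for i in range(1, b1 + 1)
        for j in range(1, b2 + 1)
        for k in range(1, b3 + 1)
        for l in range(1, b4 + 1)
    ]
    return leaves


def _unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=n)
    return v / np.linalg.norm(v)


def _build_prototypes(
    config: SynthConfig, leaves: list[ECNumber], rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Hierarchical class prototypes for both modalities.

    Each tree node adds an increment of magnitude separation *
    level_scales[k] to its parent's prototype.  The increment has a common
    component (weight sqrt(rho); the 3Di stream sees it through a fixed
    orthogonal map) and modality-private components (weight sqrt(1 - rho)),
    so with rho < 1 part of every class distinction lives in only one
    modality and zeroing a stream genuinely discards signal.  Level-4
    child directions interpolate between parent-shared directions (weight
    sqrt(parent_dependence)) and leaf-private ones: at strength 1 a leaf is
    identifiable only as the conjunction "level-3 parent x shared child
    direction", the regime where conditioning on the parent prediction is
    informative.
    """
    n = config.n_features
    s = config.separation
    rot = np.linalg.qr(rng.normal(size=(n, n)))[0]  # fixed orthogonal map
    pd = config.parent_dependence
    w_common, w_priv = np.sqrt(config.rho), np.sqrt(1.0 - config.rho)
    shared = {
        name: [_unit(rng, n) for _ in range(config.branching[3])]
        for name in ("common", "seq", "tdi")
    }

    seq_proto: dict[str, np.ndarray] = {"": np.zeros(n)}
    tdi_proto: dict[str, np.ndarray] = {"": np.zeros(n)}

    def draw_pair(scale: float, child_index: int | None) -> tuple[np.ndarray, np.ndarray]:
        if child_index is not None and pd > 0:
            mix = lambda name: (
                np.sqrt(pd) * shared[name][child_index] + np.sqrt(1 - pd) * _unit(rng, n)
            )
            common, seq_priv, tdi_priv = mix("common"), mix("seq"), mix("tdi")
        else:
            common, seq_priv, tdi_priv = _unit(rng, n), _unit(rng, n), _unit(rng, n)
        seq_inc = scale * (w_common * common + w_priv * seq_priv)
        tdi_inc = scale * (w_common * (rot @ common) + w_priv * tdi_priv)
        return seq_inc, tdi_inc

    def ensure(prefix: str, level: int, child_index: int) -> None:
        if prefix in seq_proto:
            return
        parent = prefix.rsplit(".", 1)[0] if "." in prefix else ""
        ensure_parent(parent)
        scale = s * config.level_scales[level - 1]
        seq_inc, tdi_inc = draw_pair(scale, child_index if level == 4 else None)
        seq_proto[prefix] = seq_proto[parent] + seq_inc
        tdi_proto[prefix] = tdi_proto[parent] + tdi_inc

    def ensure_parent(prefix: str) -> None:
        if prefix in seq_proto:
            return
        digits = prefix.split(".")
        ensure(prefix, len(digits), int(digits[-1]) - 1)

    # deterministic traversal order: sorted leaves, levels root-first
    for leaf in sorted(leaves):
        digits = [str(v) for v in leaf.levels]
        for k in range(1, 5):
            ensure(".".join(digits[:k]), k, leaf.levels[k - 1] - 1)

    # The planted functional-site signal is the leaf's own level-4 increment
    # direction, amplified by motif_strength: among sibling leaves the exact
    # (serial-number) identity is carried most strongly at the functional
    # site, mirroring how catalytic-site residues determine the precise
    # reaction while the global fold reflects the coarser classes.
    leaf_keys = [str(leaf) for leaf in leaves]
    motif_seq: dict[str, np.ndarray] = {}
    motif_tdi: dict[str, np.ndarray] = {}
    for key in leaf_keys:
        parent = key.rsplit(".", 1)[0]
        inc_seq = seq_proto[key] - seq_proto[parent]
        inc_tdi = tdi_proto[key] - tdi_proto[parent]
        norm_seq = np.linalg.norm(inc_seq) or 1.0
        norm_tdi = np.linalg.norm(inc_tdi) or 1.0
        motif_seq[key] = s * config.motif_strength * inc_seq / norm_seq
        motif_tdi[key] = s * config.motif_strength * inc_tdi / norm_tdi
    return seq_proto, tdi_proto, motif_seq, motif_tdi


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Draw a full synthetic dataset under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    leaves = generate_label_tree(config)
    seq_proto, tdi_proto, motif_seq, motif_tdi = _build_prototypes(config, leaves, rng)
    letter_proj = rng.normal(size=(config.n_features, len(TDI_ALPHABET)))

    records: list[tuple[EmbeddingPair, list[ECNumber]]] = []
    motif_spans: dict[str, tuple[int, int]] = {}
    leaf_of: dict[str, str] = {}
    sequences: dict[str, str] = {}
    tdi_strings: dict[str, str] = {}

    counter = 0
    for leaf in leaves:
        key = str(leaf)
        prefix3 = key.rsplit(".", 1)[0]
        siblings = [str(l) for l in leaves if str(l).rsplit(".", 1)[0] == prefix3 and str(l) != key]
        for _ in range(config.proteins_per_leaf):
            pid = f"P{counter:05d}"
            counter += 1
            L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            labels = [leaf]
            w_seq, w_tdi = seq_proto[key].copy(), tdi_proto[key].copy()
            m_seq, m_tdi = motif_seq[key], motif_tdi[key]
            if siblings and rng.random() < config.multi_label_p:
                sib = siblings[int(rng.integers(len(siblings)))]
                labels = sorted([leaf, parse_ec(sib)])
                # mixture of the two leaves' level-4 signals
                w_seq = 0.5 * (seq_proto[key] + seq_proto[sib])
                w_tdi = 0.5 * (tdi_proto[key] + tdi_proto[sib])
                m_seq = 0.5 * (motif_seq[key] + motif_seq[sib])
                m_tdi = 0.5 * (motif_tdi[key] + motif_tdi[sib])
            seq_emb = w_seq + config.noise_sigma * rng.normal(size=(L, config.n_features))
            tdi_emb = w_tdi + config.noise_sigma * rng.normal(size=(L, config.n_features))
            start = int(rng.integers(0, L - config.motif_len + 1))
            seq_emb[start : start + config.motif_len] += m_seq
            tdi_emb[start : start + config.motif_len] += m_tdi
            motif_spans[pid] = (start + 1, start + config.motif_len)  # 1-based inclusive
            leaf_of[pid] = key
            sequences[pid] = "".join(
                AA_ALPHABET[i] for i in rng.integers(len(AA_ALPHABET), size=L)
            )
            # 3Di letters follow the 3Di embedding rows through a fixed projection
            letters = np.argmax(tdi_emb @ letter_proj, axis=1)
            tdi_strings[pid] = "".join(TDI_ALPHABET[i] for i in letters)
            records.append((EmbeddingPair(pid, seq_emb, tdi_emb), labels))

    spaces = build_label_spaces([[leaf] for leaf in leaves])
    freq: dict[str, int] = {}
    for _, ecs in records:
        for ec in ecs:
            freq[str(ec)] = freq.get(str(ec), 0) + 1
    dataset = Dataset(records=records, label_spaces=spaces, ec_frequency=freq)
    leaf_keys = [str(l) for l in leaves]
    return SynthDataset(
        dataset=dataset,
        motif_spans=motif_spans,
        leaf_of=leaf_of,
        seq_prototypes={k: seq_proto[k] for k in leaf_keys},
        tdi_prototypes={k: tdi_proto[k] for k in leaf_keys},
        sequences=sequences,
        tdi_strings=tdi_strings,
        config=config,
    )


def generate_3di_pair(
    length: int, error_rate: float, seed: int | np.random.Generator = 0
) -> tuple[str, str]:
    """A reference 3Di string and a copy corrupted at rate ``error_rate``.

    Corrupted positions are substituted uniformly over the 19 other letters,
    so the expected recovery rate is exactly 1 - error_rate.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref_idx = rng.integers(len(TDI_ALPHABET), size=length)
    corrupt = rng.random(length) < error_rate
    shifts = rng.integers(1, len(TDI_ALPHABET), size=length)
    out_idx = np.where(corrupt, (ref_idx + shifts) % len(TDI_ALPHABET), ref_idx)
    ref = "".join(TDI_ALPHABET[i] for i in ref_idx)
    pred = "".join(TDI_ALPHABET[i] for i in out_idx)
    return ref, pred


def split_dataset(
    synth: SynthDataset, test_fraction: float, rng: np.random.Generator
) -> tuple[Dataset, Dataset]:
    """Leaf-stratified train/test split; both halves share the label spaces."""
    by_leaf: dict[str, list[int]] = {}
    for i, (pair, _) in enumerate(synth.dataset.records):
        by_leaf.setdefault(synth.leaf_of[pair.protein_id], []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for leaf in sorted(by_leaf):
        idx = np.array(by_leaf[leaf])
        perm = rng.permutation(len(idx))
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[perm[:n_test]].tolist())
        train_idx.extend(idx[perm[n_test:]].tolist())
    train_idx.sort()
    test_idx.sort()

    def subset(indices: list[int]) -> Dataset:
        records = [synth.dataset.records[i] for i in indices]
        freq: dict[str, int] = {}
        for _, ecs in records:
            for ec in ecs:
                freq[str(ec)] = freq.get(str(ec), 0) + 1
        return Dataset(records=records, label_spaces=synth.dataset.label_spaces, ec_frequency=freq)

    return subset(train_idx), subset(test_idx)


def write_fixture(synth: SynthDataset, out_dir: str | Path) -> dict[str, str]:
    """Emit the dataset in the pipeline's on-disk formats, with a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "sequences.fasta", synth.sequences)
    write_fasta(out / "tdi.fasta", synth.tdi_strings)
    write_embeddings(out / "embeddings.h5", [pair for pair, _ in synth.dataset.records])
    write_labels_tsv(
        out / "labels.tsv", {pair.protein_id: ecs for pair, ecs in synth.dataset.records}
    )
    with open(out / "motifs.tsv", "w") as fh:
        fh.write("protein_id\tmotif_start\tmotif_end\n")
        for pid, (a, b) in synth.motif_spans.items():
            fh.write(f"{pid}\t{a}\t{b}\n")
    manifest: dict[str, str] = {}
    for name in ["sequences.fasta", "tdi.fasta", "labels.tsv", "motifs.tsv"]:
        manifest[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    # hash the logical content of the HDF5 container (file bytes are not
    # stable across writes because of internal metadata)
    h = hashlib.sha256()
    for pair, _ in synth.dataset.records:
        h.update(pair.protein_id.encode())
        h.update(pair.seq_embedding.astype(np.float32).tobytes())
        h.update(pair.tdi_embedding.astype(np.float32).tobytes())
    manifest["embeddings.h5"] = h.hexdigest()
    manifest["config"] = json.dumps(synth.config.to_dict(), sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
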