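"""Readers and writers for sequences, 3Di strings, embeddings and labels.

Embeddings are per-residue feature matrices (one row per residue, fixed
feature width) for both modalities — in production these come from protein
language models over the amino-acid and 3Di alphabets; this package treats
the embedder as a pluggable upstream step and only defines the container
contract.  Storage is a single HDF5 file with one group per protein id
holding float datasets ``seq`` and ``tdi`` of identical shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

from .ontology import ECNumber, LabelSpaces, build_label_spaces, parse_ec_cell

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingPair:
    """Per-residue embeddings of one protein in both modalities (L x N each)."""

    protein_id: str
    seq_embedding: np.ndarray
    tdi_embedding: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.seq_embedding, dtype=np.float64)
        t = np.asarray(self.tdi_embedding, dtype=np.float64)
        if s.ndim != 2 or t.ndim != 2:
            raise ValueError(f"{self.protein_id}: embeddings must be 2-D matrices")
        if s.shape != t.shape:
            raise ValueError(
                f"{self.protein_id}: seq/3Di embedding shape mismatch {s.shape} vs {t.shape}"
            )
        if s.shape[0] < 1:
            raise ValueError(f"{self.protein_id}: empty embedding (L = 0)")
        if not (np.isfinite(s).all() and np.isfinite(t).all()):
            raise ValueError(f"{self.protein_id}: non-finite embedding values")
        self.seq_embedding = s
        self.tdi_embedding = t

    @property
    def length(self) -> int:
        return self.seq_embedding.shape[0]

    @property
    def width(self) -> int:
        return self.seq_embedding.shape[1]


@dataclass
class Dataset:
    """Aligned (embedding pair, EC set) records plus label bookkeeping."""

    records: list[tuple[EmbeddingPair, list[ECNumber]]]
    label_spaces: LabelSpaces
    ec_frequency: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [pair.protein_id for pair, _ in self.records]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercased sequence map.

    Used for both amino-acid sequences and 3Di token strings (both are
    20-letter alphabets).  Duplicate ids and empty records are errors.
    """
    result: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in result:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        result[rec.id] = seq
    return result


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_embeddings(path: str | Path, pairs: Iterable[EmbeddingPair]) -> None:
    """Write embedding pairs to HDF5: one group per id, datasets seq/tdi (float32)."""
    with h5py.File(path, "w") as f:
        for pair in pairs:
            grp = f.create_group(pair.protein_id)
            grp.create_dataset("seq", data=pair.seq_embedding.astype(np.float32), track_times=False)
            grp.create_dataset("tdi", data=pair.tdi_embedding.astype(np.float32), track_times=False)


def read_embeddings(path: str | Path, ids: Sequence[str] | None = None) -> dict[str, EmbeddingPair]:
    """Read embedding pairs for ``ids`` (all groups when None).

    Missing ids are reported collectively; shape mismatches and non-finite
    values are rejected per protein.
    """
    out: dict[str, EmbeddingPair] = {}
    with h5py.File(path, "r") as f:
        wanted = list(ids) if ids is not None else list(f.keys())
        missing = [pid for pid in wanted if pid not in f]
        if missing:
            raise KeyError(f"ids missing from {path}: {missing}")
        for pid in wanted:
            grp = f[pid]
            out[pid] = EmbeddingPair(pid, grp["seq"][...], grp["tdi"][...])
    return out


def read_labels_tsv(path: str | Path) -> dict[str, list[ECNumber]]:
    """Read a ``protein_id<TAB>EC;EC;...`` table (Swiss-Prot multi-EC style)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "ec"], dtype=str)
    if df["protein_id"].duplicated().any():
        dups = df["protein_id"][df["protein_id"].duplicated()].tolist()
        raise ValueError(f"duplicate protein ids in {path}: {dups}")
    return {row.protein_id: parse_ec_cell(row.ec) for row in df.itertuples()}


def write_labels_tsv(path: str | Path, labels: Mapping[str, Sequence[ECNumber]]) -> None:
    with open(path, "w") as fh:
        for pid, ecs in labels.items():
            fh.write(f"{pid}\t{'; '.join(str(e) for e in ecs)}\n")


def assemble_dataset(
    fasta_path: str | Path,
    tdi_fasta_path: str | Path,
    embeddings_path: str | Path,
    labels_path: str | Path,
    label_spaces: LabelSpaces | None = None,
) -> Dataset:
    """Inner-join sequences, 3Di strings, embeddings and labels on protein id.

    Proteins missing from any source are dropped and logged.  Amino-acid /
    3Di / embedding lengths must agree exactly for retained proteins —
    silent truncation would misalign residue-level attention maps.  The
    per-EC training frequency (number of proteins carrying each exact EC) is
    recorded for frequency-binned evaluation.  Pass ``label_spaces`` to
    encode a held-out set against the training vocabularies.
    """
    seqs = read_fasta(fasta_path)
    tdis = read_fasta(tdi_fasta_path)
    labels = read_labels_tsv(labels_path)
    common = sorted(set(seqs) & set(tdis) & set(labels))
    if not common:
        raise ValueError("no protein id is present in all of: FASTA, 3Di FASTA, labels")
    dropped = sorted((set(seqs) | set(tdis) | set(labels)) - set(common))
    if dropped:
        logger.info("assemble_dataset: dropping %d ids absent from some source: %s",
                    len(dropped), dropped[:10])
    pairs = read_embeddings(embeddings_path, common)
    records: list[tuple[EmbeddingPair, list[ECNumber]]] = []
    for pid in common:
        pair = pairs[pid]
        if len(seqs[pid]) != pair.length or len(tdis[pid]) != pair.length:
            raise ValueError(
                f"{pid}: sequence length {len(seqs[pid])} / 3Di length {len(tdis[pid])} "
                f"do not match embedding rows {pair.length}"
            )
        records.append((pair, labels[pid]))
    spaces = label_spaces or build_label_spaces(ecs for _, ecs in records)
    freq: dict[str, int] = {}
    for _, ecs in records:
        for ec in ecs:
            freq[str(ec)] = freq.get(str(ec), 0) + 1
    return Dataset(records=records, label_spaces=spaces, ec_frequency=freq)
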