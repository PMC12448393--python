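"""EC-number parsing and hierarchical label spaces.

An EC number is a four-level code ``class.subclass.sub-subclass.serial``
(e.g. ``2.7.7.7``); a single enzyme may carry several.  The classifier does
not predict the four digits as independent symbols: the level-*k* label
space is the set of distinct *k*-digit prefixes observed in training, so
that a level-4 label determines its whole ancestor chain.  This prefix
encoding is what makes per-digit evaluation and prefix-consistent decoding
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

LEVELS = 4


class ECParseError(ValueError):
    """Raised when a string is not a fully resolved four-digit EC number."""


class UnknownLabelError(KeyError):
    """Raised when an EC (or one of its prefixes) is absent from the label spaces."""


@dataclass(frozen=True, order=True)
class ECNumber:
    """A fully resolved EC number; each level is a positive integer.

    Level values may exceed 9 (serial numbers such as ``2.1.1.359``).
    """

    level1: int
    level2: int
    level3: int
    level4: int

    def __post_init__(self):
        for v in self.levels:
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ECParseError(f"EC levels must be positive integers, got {self!r}")

    @property
    def levels(self) -> tuple[int, int, int, int]:
        return (self.level1, self.level2, self.level3, self.level4)

    def __str__(self) -> str:
        return ".".join(str(v) for v in self.levels)


def parse_ec(text: str) -> ECNumber:
    """Parse a dotted EC string such as ``"2.1.1.359"``.

    Partial or placeholder codes (``"1.2.3.-"``, ``"2.7.7.n1"``) are
    rejected: the predictor is trained only on fully resolved labels.
    """
    if not isinstance(text, str):
        raise ECParseError(f"expected a string, got {type(text).__name__}")
    cleaned = text.strip()
    if cleaned.upper().startswith("EC"):
        cleaned = cleaned[2:].strip().lstrip(":").strip()
    tokens = cleaned.split(".")
    if len(tokens) != LEVELS:
        raise ECParseError(f"{text!r}: expected 4 dot-separated digits, got {len(tokens)}")
    values = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            raise ECParseError(f"{text!r}: empty digit token")
        if not tok.isdigit():
            raise ECParseError(f"{text!r}: non-numeric or placeholder token {tok!r}")
        v = int(tok)
        if v < 1:
            raise ECParseError(f"{text!r}: digit values must be >= 1")
        values.append(v)
    return ECNumber(*values)


def ec_prefix(ec: ECNumber, k: int) -> str:
    """The first ``k`` digits of ``ec`` as a canonical dotted key (1 <= k <= 4)."""
    if not 1 <= k <= LEVELS:
        raise ValueError(f"prefix level must be in 1..4, got {k}")
    return ".".join(str(v) for v in ec.levels[:k])


@dataclass
class LabelSpaces:
    """Per-level vocabularies of EC prefixes, with parent links.

    ``vocab[k-1]`` is the sorted list of distinct k-digit prefixes seen in
    training; ``index[k-1]`` maps prefix -> position; ``parent[k-1]`` maps a
    level-k prefix to its level-(k-1) parent (``parent[0]`` is empty).
    Sorting is lexicographic on the numeric digit tuple, so index assignment
    is deterministic across runs and input orderings.
    """

    vocab: list[list[str]]
    index: list[dict[str, int]] = field(default_factory=list)
    parent: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.index:
            self.index = [{lab: i for i, lab in enumerate(v)} for v in self.vocab]
        if not self.parent:
            self.parent = [
                {} if k == 0 else {lab: lab.rsplit(".", 1)[0] for lab in self.vocab[k]}
                for k in range(LEVELS)
            ]

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return tuple(len(v) for v in self.vocab)  # type: ignore[return-value]

    def children(self, level: int, label: str) -> list[str]:
        """Level-(level+1) labels whose parent is ``label`` (level is 1-based)."""
        return [lab for lab in self.vocab[level] if self.parent[level][lab] == label]

    def to_dict(self) -> dict:
        return {"vocab": self.vocab}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LabelSpaces":
        return cls(vocab=[list(v) for v in d["vocab"]])


def _prefix_sort_key(label: str) -> tuple[int, ...]:
    return tuple(int(t) for t in label.split("."))


def build_label_spaces(ec_lists: Iterable[Iterable[ECNumber]]) -> LabelSpaces:
    """Collect the distinct k-digit prefixes of every training EC, per level.

    Input order is irrelevant: vocabularies are sorted on the numeric digit
    tuple.  By construction every level-k entry's (k-1)-prefix is present at
    level k-1, and vocabulary sizes are non-decreasing with level.
    """
    per_level: list[set[str]] = [set() for _ in range(LEVELS)]
    n = 0
    for ecs in ec_lists:
        for ec in ecs:
            n += 1
            for k in range(1, LEVELS + 1):
                per_level[k - 1].add(ec_prefix(ec, k))
    if n == 0:
        raise ValueError("cannot build label spaces from an empty EC collection")
    vocab = [sorted(s, key=_prefix_sort_key) for s in per_level]
    return LabelSpaces(vocab=vocab)


@dataclass
class TargetEncoding:
    """Per-level multi-hot target vectors over the LabelSpaces vocabularies."""

    levels: list[np.ndarray]  # four float64 vectors of 0/1

    def active_counts(self) -> tuple[int, ...]:
        return tuple(int(v.sum()) for v in self.levels)


def encode_targets(ec_set: Iterable[ECNumber], spaces: LabelSpaces) -> TargetEncoding:
    """Multi-hot encode an enzyme's EC set: level-k actives are its k-prefixes.

    Unknown prefixes raise :class:`UnknownLabelError` rather than being
    silently dropped.
    """
    ecs = list(ec_set)
    if not ecs:
        raise ValueError("an annotated enzyme must carry at least one EC number")
    vecs = [np.zeros(len(v)) for v in spaces.vocab]
    for ec in ecs:
        for k in range(1, LEVELS + 1):
            key = ec_prefix(ec, k)
            idx = spaces.index[k - 1].get(key)
            if idx is None:
                raise UnknownLabelError(f"label {key!r} (level {k}) not in label spaces")
            vecs[k - 1][idx] = 1.0
    return TargetEncoding(levels=vecs)


def parse_ec_cell(cell: str) -> list[ECNumber]:
    """Parse a Swiss-Prot style multi-EC cell, e.g. ``"2.1.1.359; 2.1.1.354"``."""
    ecs = [parse_ec(tok) for tok in cell.split(";") if tok.strip()]
    if not ecs:
        raise ECParseError(f"empty EC cell: {cell!r}")
    return ecs
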