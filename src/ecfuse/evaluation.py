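"""Evaluation: set-based P/R/F1, per-digit metrics, frequency binning,
the 3Di recovery-rate statistic, and the ablation harness.

Protein-level metrics treat each protein's predicted and true EC sets as
sets: P = |intersection|/|predicted|, R = |intersection|/|true|, F1 their
harmonic mean.  Macro averaging (the default report) averages the
per-protein values; micro averaging pools the intersection/prediction/truth
counts over all proteins.  Per-digit metrics repeat the computation on the
deduplicated k-prefix sets, which makes level-k F1 non-increasing in k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ontology import LEVELS, ec_prefix, parse_ec


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    n_proteins: int
    mode: str  # "macro" | "micro"

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_proteins": self.n_proteins,
            "mode": self.mode,
        }


def _prf(n_inter: int, n_pred: int, n_true: int) -> tuple[float, float, float]:
    p = n_inter / n_pred if n_pred else 0.0
    r = n_inter / n_true if n_true else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def protein_level_metrics(
    pred: dict[str, set[str]], truth: dict[str, set[str]], mode: str = "macro"
) -> MetricsReport:
    """Set-overlap precision/recall/F1 over a shared id universe."""
    if set(pred) != set(truth):
        only_p = sorted(set(pred) - set(truth))[:5]
        only_t = sorted(set(truth) - set(pred))[:5]
        raise ValueError(f"id universes differ (pred-only {only_p}, truth-only {only_t})")
    if mode not in ("macro", "micro"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    ids = sorted(truth)
    if mode == "micro":
        n_i = sum(len(pred[i] & truth[i]) for i in ids)
        n_p = sum(len(pred[i]) for i in ids)
        n_t = sum(len(truth[i]) for i in ids)
        p, r, f1 = _prf(n_i, n_p, n_t)
    else:
        ps, rs, f1s = [], [], []
        for i in ids:
            pi, ri, fi = _prf(len(pred[i] & truth[i]), len(pred[i]), len(truth[i]))
            ps.append(pi)
            rs.append(ri)
            f1s.append(fi)
        p, r, f1 = float(np.mean(ps)), float(np.mean(rs)), float(np.mean(f1s))
    return MetricsReport(p, r, f1, len(ids), mode)


def per_digit_metrics(
    pred: dict[str, set[str]], truth: dict[str, set[str]], mode: str = "macro"
) -> list[MetricsReport]:
    """Level-k metrics on the deduplicated k-prefix sets, for k = 1..4."""
    reports = []
    for k in range(1, LEVELS + 1):
        pred_k = {pid: {ec_prefix(parse_ec(e), k) for e in ecs} for pid, ecs in pred.items()}
        truth_k = {pid: {ec_prefix(parse_ec(e), k) for e in ecs} for pid, ecs in truth.items()}
        reports.append(protein_level_metrics(pred_k, truth_k, mode))
    return reports


@dataclass
class BinnedReport:
    edges: list[float]  # half-open-left bins (edges[i], edges[i+1]]
    f1: list[float]
    counts: list[int]

    def to_dict(self) -> dict:
        return {"edges": self.edges, "f1": self.f1, "counts": self.counts}


def default_bin_edges(max_freq: int, width: int = 5) -> list[float]:
    """(0, 5], (5, 10], ... covering the largest observed frequency."""
    top = int(np.ceil(max(max_freq, 1) / width)) * width
    return [0] + list(range(width, top + width, width))


def per_label_f1(pred: dict[str, set[str]], truth: dict[str, set[str]]) -> dict[str, float]:
    """Label-level F1 per EC: each (protein, EC) incidence is one binary decision."""
    labels = sorted({e for s in pred.values() for e in s} | {e for s in truth.values() for e in s})
    out: dict[str, float] = {}
    for lab in labels:
        tp = sum(1 for pid in truth if lab in pred[pid] and lab in truth[pid])
        fp = sum(1 for pid in truth if lab in pred[pid] and lab not in truth[pid])
        fn = sum(1 for pid in truth if lab not in pred[pid] and lab in truth[pid])
        out[lab] = 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 0.0
    return out


def bin_by_frequency(
    label_f1: dict[str, float],
    train_freqs: dict[str, int],
    edges: list[float] | None = None,
) -> BinnedReport:
    """Aggregate per-EC F1 into training-frequency bins ``(lo, hi]``.

    Every evaluated EC must have a recorded training frequency; ECs never
    seen in training fall in the first bin (frequency 0 is inside (0, w]
    only if > 0, so zero-frequency labels are rejected explicitly).
    """
    missing = [lab for lab in label_f1 if lab not in train_freqs]
    if missing:
        raise KeyError(f"no training frequency recorded for: {missing[:10]}")
    if edges is None:
        edges = default_bin_edges(max(train_freqs[lab] for lab in label_f1))
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    sums = [0.0] * (len(edges) - 1)
    counts = [0] * (len(edges) - 1)
    for lab, f1 in label_f1.items():
        freq = train_freqs[lab]
        placed = False
        for b in range(len(edges) - 1):
            if edges[b] < freq <= edges[b + 1]:
                sums[b] += f1
                counts[b] += 1
                placed = True
                break
        if not placed:
            raise ValueError(f"frequency {freq} of {lab} outside the bin range {edges}")
    f1s = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    return BinnedReport(edges=list(edges), f1=f1s, counts=counts)


# ------------------------------------------------------------- 3Di recovery
def recovery_rate(predicted_3di: str, reference_3di: str) -> float:
    """Fraction of positions where the predicted 3Di letter matches the reference."""
    if not predicted_3di or not reference_3di:
        raise ValueError("empty 3Di string")
    if len(predicted_3di) != len(reference_3di):
        raise ValueError(
            f"length mismatch: {len(predicted_3di)} vs {len(reference_3di)}"
        )
    matches = sum(a == b for a, b in zip(predicted_3di, reference_3di))
    return matches / len(reference_3di)


def recovery_summary(rates, ddof: int = 1) -> dict[str, float]:
    """Mean, sd, min, max and median of a collection of recovery rates.

    ``ddof=1`` (sample sd) is the default; pass 0 for the population sd.
    """
    arr = np.asarray(list(rates), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no recovery rates supplied")
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return {
        "mean": float(arr.mean()),
        "sd": sd,
        "min": float(arr.min()),
        "max": float(arr.max()),
        "median": float(np.median(arr)),
    }


# ----------------------------------------------------------------- ablations
ABLATION_SWITCHES = ("full", "no_global", "no_local", "no_autoregressive",
                     "seq_only", "tdi_only", "no_triplet")


def run_ablation(
    train_dataset,
    test_dataset,
    variants: list[str],
    estimator_kwargs: dict | None = None,
    seeds: list[int] | None = None,
) -> dict[str, dict]:
    """Retrain the classifier from scratch under each ablation switch.

    Variants: ``full`` (reference), ``no_global`` (identity pass-through of
    the raw streams), ``no_local`` (global-only fusion), ``no_autoregressive``
    (four independent per-level MLPs), ``seq_only`` / ``tdi_only`` (the other
    modality zeroed at input), ``no_triplet`` (phase 1 skipped).  Every
    variant is trained once per seed with the shared seed list; the report
    holds per-seed macro metrics and their mean.
    """
    from .estimator import DualPathwayECClassifier  # local import: avoid a cycle

    estimator_kwargs = dict(estimator_kwargs or {})
    seeds = list(seeds) if seeds is not None else [0]
    unknown = [v for v in variants if v not in ABLATION_SWITCHES]
    if unknown:
        raise ValueError(f"unknown ablation switches: {unknown}")
    report: dict[str, dict] = {}
    for variant in variants:
        kwargs = dict(estimator_kwargs)
        if variant == "no_global":
            kwargs["use_global"] = False
        elif variant == "no_local":
            kwargs["use_local"] = False
        elif variant == "no_autoregressive":
            kwargs["autoregressive"] = False
        elif variant == "seq_only":
            kwargs["modality"] = "seq"
        elif variant == "tdi_only":
            kwargs["modality"] = "tdi"
        elif variant == "no_triplet":
            kwargs["use_triplet_pretraining"] = False
        rows = []
        for seed in seeds:
            clf = DualPathwayECClassifier(random_state=seed, **kwargs)
            clf.fit_dataset(train_dataset)
            pred = clf.predict_dataset(test_dataset)
            truth = {
                pair.protein_id: {str(e) for e in ecs} for pair, ecs in test_dataset.records
            }
            macro = protein_level_metrics(pred, truth, "macro")
            per_digit = per_digit_metrics(pred, truth, "macro")
            rows.append(
                {
                    "seed": seed,
                    "precision": macro.precision,
                    "recall": macro.recall,
                    "f1": macro.f1,
                    "per_digit_f1": [r.f1 for r in per_digit],
                }
            )
        report[variant] = {
            "per_seed": rows,
            "mean_f1": float(np.mean([r["f1"] for r in rows])),
            "mean_level4_f1": float(np.mean([r["per_digit_f1"][3] for r in rows])),
        }
    return report


def write_ablation_tsv(path, report: dict[str, dict]) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tmean_f1\tmean_level4_f1\tn_seeds\n")
        for variant, row in report.items():
            fh.write(
                f"{variant}\t{row['mean_f1']:.4f}\t{row['mean_level4_f1']:.4f}"
                f"\t{len(row['per_seed'])}\n"
            )
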