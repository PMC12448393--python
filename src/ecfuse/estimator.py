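"""Scikit-learn style estimator wrapping the full pipeline.

:class:`DualPathwayECClassifier` is fit/predict-shaped: ``fit`` consumes
per-protein embedding pairs with EC-number labels, runs the two-phase
training (contrastive extractor pre-training, then frozen-extractor head
training), and ``predict`` returns prefix-consistent EC sets.  It follows
scikit-learn conventions — constructor arguments are hyperparameters stored
verbatim (so ``get_params``/``set_params``/``clone`` work), fitted state
lives in trailing-underscore attributes, and inputs are validated in
``fit`` — but the samples are variable-length embedding matrices rather
than a rectangular design matrix, so it composes with sklearn model
selection only through its own scoring helpers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .features import (
    ModelConfig,
    attention_importance,
    extract_features,
    init_extractor_params,
)
from .io import Dataset, EmbeddingPair
from .ontology import ECNumber, LabelSpaces, build_label_spaces, parse_ec
from .prediction import (
    PredictionResult,
    autoregressive_forward,
    decode_predictions,
    init_head_params,
)
from .training import (
    PhaseSchedule,
    TrainConfig,
    compute_pooled_features,
    train_phase1,
    train_phase2,
)


class NotFittedError(RuntimeError):
    pass


class DualPathwayECClassifier(BaseEstimator):
    """Hierarchical multi-label EC-number classifier over embedding pairs.

    Parameters mirror the architecture and training recipe: ``n_heads``
    attention heads across ``n_blocks`` global and local blocks with
    ``kernel_sizes`` convolutions; a four-level autoregressive sigmoid head
    decoded at ``threshold`` with a greedy fallback.  The default schedules
    are desk-scale (minutes on one CPU); the published large-scale recipe is
    available as a configuration profile for the command-line interface.

    ``modality`` restricts the input to one stream ("seq" or "tdi", the
    other is zeroed); ``use_global`` / ``use_local`` / ``autoregressive`` /
    ``use_triplet_pretraining`` are the ablation switches.
    """

    def __init__(
        self,
        n_heads: int = 2,
        n_blocks: int = 3,
        kernel_sizes: tuple[int, ...] = (7, 9, 11),
        threshold: float = 0.5,
        margin: float = 1.0,
        use_global: bool = True,
        use_local: bool = True,
        autoregressive: bool = True,
        modality: str | None = None,
        use_triplet_pretraining: bool = True,
        swap_layer1_roles: bool = False,
        phase1_epochs: int = 10,
        phase1_batch_size: int = 40,
        phase1_lr: float = 5e-4,
        triplets_per_epoch: int = 80,
        phase2_epochs: int = 800,
        phase2_batch_size: int = 96,
        phase2_lr: float = 1e-3,
        cosine_annealing: bool = True,
        scheduled_sampling: float = 0.0,
        random_state: int = 0,
    ):
        self.n_heads = n_heads
        self.n_blocks = n_blocks
        self.kernel_sizes = kernel_sizes
        self.threshold = threshold
        self.margin = margin
        self.use_global = use_global
        self.use_local = use_local
        self.autoregressive = autoregressive
        self.modality = modality
        self.use_triplet_pretraining = use_triplet_pretraining
        self.swap_layer1_roles = swap_layer1_roles
        self.phase1_epochs = phase1_epochs
        self.phase1_batch_size = phase1_batch_size
        self.phase1_lr = phase1_lr
        self.triplets_per_epoch = triplets_per_epoch
        self.phase2_epochs = phase2_epochs
        self.phase2_batch_size = phase2_batch_size
        self.phase2_lr = phase2_lr
        self.cosine_annealing = cosine_annealing
        self.scheduled_sampling = scheduled_sampling
        self.random_state = random_state

    # ------------------------------------------------------------- plumbing
    def _as_pair(self, x, index: int) -> EmbeddingPair:
        if isinstance(x, EmbeddingPair):
            pair = x
        else:
            seq, tdi = x
            pair = EmbeddingPair(f"X{index:05d}", seq, tdi)
        if self.modality is None:
            return pair
        if self.modality == "seq":
            return EmbeddingPair(pair.protein_id, pair.seq_embedding,
                                 np.zeros_like(pair.tdi_embedding))
        if self.modality == "tdi":
            return EmbeddingPair(pair.protein_id, np.zeros_like(pair.seq_embedding),
                                 pair.tdi_embedding)
        raise ValueError(f"modality must be None, 'seq' or 'tdi', got {self.modality!r}")

    @staticmethod
    def _as_ec_list(y_item) -> list[ECNumber]:
        if isinstance(y_item, str):
            tokens = [t for t in y_item.split(";") if t.strip()]
        else:
            tokens = list(y_item)
        ecs = [t if isinstance(t, ECNumber) else parse_ec(str(t)) for t in tokens]
        if not ecs:
            raise ValueError("every training protein needs at least one EC label")
        return ecs

    def _to_dataset(self, X: Sequence, y: Sequence, spaces: LabelSpaces | None) -> Dataset:
        if len(X) != len(y):
            raise ValueError(f"X and y lengths differ: {len(X)} vs {len(y)}")
        if len(X) == 0:
            raise ValueError("empty training set")
        records = []
        for i, (x, yi) in enumerate(zip(X, y)):
            records.append((self._as_pair(x, i), self._as_ec_list(yi)))
        widths = {pair.width for pair, _ in records}
        if len(widths) != 1:
            raise ValueError(f"inconsistent embedding widths: {sorted(widths)}")
        spaces = spaces or build_label_spaces(ecs for _, ecs in records)
        freq: dict[str, int] = {}
        for _, ecs in records:
            for ec in ecs:
                freq[str(ec)] = freq.get(str(ec), 0) + 1
        return Dataset(records=records, label_spaces=spaces, ec_frequency=freq)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            margin=self.margin,
            phase1=PhaseSchedule(self.phase1_epochs, self.phase1_batch_size, self.phase1_lr),
            phase2=PhaseSchedule(
                self.phase2_epochs,
                self.phase2_batch_size,
                self.phase2_lr,
                cosine_annealing=self.cosine_annealing,
            ),
            triplets_per_epoch=self.triplets_per_epoch,
            scheduled_sampling=self.scheduled_sampling,
            seed=self.random_state,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "extractor_params_"):
            raise NotFittedError("this DualPathwayECClassifier instance is not fitted yet")

    # ------------------------------------------------------------------ fit
    def fit(self, X: Sequence, y: Sequence) -> "DualPathwayECClassifier":
        """Fit on embedding pairs X and EC label sets y.

        X: sequence of EmbeddingPair or (seq_matrix, tdi_matrix) tuples.
        y: per-protein EC labels — iterables of EC strings/ECNumbers, or a
        single ``"a.b.c.d; e.f.g.h"`` style string.
        """
        return self.fit_dataset(self._to_dataset(X, y, spaces=None))

    def fit_dataset(self, dataset: Dataset) -> "DualPathwayECClassifier":
        """Fit directly on an assembled :class:`~ecfuse.io.Dataset`."""
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        width = dataset.records[0][0].width
        cfg = ModelConfig(
            n_features=width,
            n_heads=self.n_heads,
            n_blocks=self.n_blocks,
            kernel_sizes=tuple(self.kernel_sizes),
            use_global=self.use_global,
            use_local=self.use_local,
            swap_layer1_roles=self.swap_layer1_roles,
        )
        if self.modality is not None:
            dataset = Dataset(
                records=[(self._as_pair(pair, i), ecs)
                         for i, (pair, ecs) in enumerate(dataset.records)],
                label_spaces=dataset.label_spaces,
                ec_frequency=dataset.ec_frequency,
            )
        train_cfg = self._train_config()
        rng = np.random.default_rng(self.random_state)
        extractor = init_extractor_params(cfg, rng)
        head = init_head_params(cfg.fused_width, dataset.label_spaces, rng, self.autoregressive)
        trace: list[dict] = []
        if self.use_triplet_pretraining:
            trace.extend(train_phase1(dataset, extractor, cfg, train_cfg, rng))
        pooled = compute_pooled_features(dataset, extractor, cfg)
        trace.extend(
            train_phase2(dataset, extractor, head, cfg, train_cfg, rng, pooled_cache=pooled)
        )
        self.model_config_ = cfg
        self.extractor_params_ = extractor
        self.head_params_ = head
        self.label_spaces_ = dataset.label_spaces
        self.loss_trace_ = trace
        self.n_features_in_ = width
        return self

    # -------------------------------------------------------------- predict
    def _pooled_of(self, X: Sequence) -> tuple[list[EmbeddingPair], np.ndarray]:
        self._check_fitted()
        pairs = [self._as_pair(x, i) for i, x in enumerate(X)]
        rows = []
        for pair in pairs:
            feats = extract_features(pair, self.extractor_params_, self.model_config_)
            rows.append(feats.pooled)
        return pairs, np.stack(rows)

    def predict_proba(self, X: Sequence) -> list[np.ndarray]:
        """Per-level sigmoid probability matrices, shape (n_samples, |vocab_k|)."""
        _, pooled = self._pooled_of(X)
        return autoregressive_forward(pooled, self.head_params_)

    def predict_results(self, X: Sequence) -> list[PredictionResult]:
        pairs, pooled = self._pooled_of(X)
        probs = autoregressive_forward(pooled, self.head_params_)
        out = []
        for i, pair in enumerate(pairs):
            per_level = [probs[k][i] for k in range(4)]
            decoded = decode_predictions(per_level, self.label_spaces_, self.threshold)
            out.append(PredictionResult(pair.protein_id, per_level, decoded))
        return out

    def predict(self, X: Sequence) -> list[set[str]]:
        """Decoded EC-string sets, one per sample (never empty)."""
        return [res.ec_set for res in self.predict_results(X)]

    def predict_dataset(self, dataset: Dataset) -> dict[str, set[str]]:
        results = self.predict_results([pair for pair, _ in dataset.records])
        return {res.protein_id: res.ec_set for res in results}

    def residue_importance(self, X: Sequence) -> list[np.ndarray]:
        """Per-residue attention importance scores in [0, 1] for each sample."""
        self._check_fitted()
        return [
            attention_importance(self._as_pair(x, i), self.extractor_params_, self.model_config_)
            for i, x in enumerate(X)
        ]

    def score(self, X: Sequence, y: Sequence) -> float:
        """Macro protein-level F1 of exact EC predictions."""
        from .evaluation import protein_level_metrics

        preds = self.predict(X)
        truth = {str(i): {str(e) for e in self._as_ec_list(yi)} for i, yi in enumerate(y)}
        pred = {str(i): p for i, p in enumerate(preds)}
        return protein_level_metrics(pred, truth, "macro").f1
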