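# Methods

This note documents the model implemented in `ecfuse`, the design choices
made where the architecture family leaves details open, the synthetic data
the package trains on, and the numerical conventions. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Problem setting

An enzyme's EC number is a four-level hierarchical code; one enzyme may
carry several (e.g. the five methyltransferase codes of PRDM9, all sharing
the `2.1.1` sub-subclass). The classifier consumes two per-residue embedding
matrices per protein — one over the amino-acid sequence, one over its 3Di
structure-token string (a 20-letter discretization of local backbone
geometry that lets tertiary structure be processed as a sequence) — and
emits a set of four-level codes. Embedding computation is out of scope: the
package defines a container contract (HDF5, one group per protein id,
float32 datasets `seq` and `tdi` of identical L×N shape) and treats the
embedder as a pluggable upstream step.

## Label encoding

The level-k label space is the set of distinct k-digit *prefixes* observed
in training, not the set of bare k-th digit values. Under prefix encoding a
level-4 label determines its whole ancestor chain, per-digit metrics are
well defined, and the per-level vocabularies are nested in size. Targets are
per-level multi-hot vectors (an enzyme's level-k actives are the k-prefixes
of its EC set), which is what makes the task multi-label at every level.
Placeholder or partial codes (`1.2.3.-`, `n1`) are rejected at ingest:
training labels must be fully resolved. Vocabularies sort on the numeric
digit tuple, so index assignment is reproducible across runs and input
orderings.

## Architecture

Widths: embedding width N (default 16 in the desk-scale profile), h
attention heads with per-head width N/h (default h = 2), 3 global and 3
local blocks, convolution kernels (7, 9, 11).

**Global blocks.** Each block applies two multi-head cross-attention layers
with scaled dot-product attention. Layer 1 treats the 3Di stream as query
and the sequence stream as key/value and updates the 3Di stream; layer 2
treats the sequence stream as query against the updated 3Di stream and
updates the sequence stream. Each layer: per-head projections, softmax
attention, concatenation, output projection, residual connection on the
updated stream, layer normalization. The residual-plus-normalization
convention is ours: six unnormalized attention layers are untrainable in
practice, and no position-wise feed-forward sublayer is added. A config
flag (`swap_layer1_roles`) selects the alternative reading in which layer-1
queries come from the sequence stream while the residual still updates the
3Di stream; the default follows the composition
`cross_attention(tdi ← seq)` then `cross_attention(seq ← tdi_hat)`.

**Local blocks.** The two L×N input channels are flattened to 2N feature
channels per position. Three parallel same-padded 1-D convolutions map
2N → N channels each; their concatenation (L×3N) passes through a
per-position MLP with one hidden layer of width 3N and relu back to L×N.
Block 1 reads the raw (sequence, 3Di) pair — the natural choice that keeps
the two-channel contract uniform; block i>1 reads (updated global sequence
feature i−1, local output i−1).

**Fusion and pooling.** `F_fuse` concatenates the final global sequence
features with the final local output (L×2N). The protein vector is the
unweighted mean over residues; pooling is needed by the prediction MLPs and
the triplet distance and the architecture family leaves it unspecified.

**Prediction head.** Four MLPs (two layers, hidden width = input width,
relu, sigmoid outputs) predict the four levels in order. MLP_1 reads the
pooled vector; MLP_j (j>1) reads the pooled vector concatenated with the
previous level's vector — the ground-truth multi-hot during training
(teacher forcing; scheduled sampling is available but off by default), the
previous sigmoid outputs at inference. The full previous *vector* is fed
rather than one decoded digit so multi-EC enzymes can keep several active
parents.

**Decoding.** A level-4 label is emitted when its own probability and its
whole ancestor chain clear the threshold τ (default 0.5); its confidence is
the chain minimum. If nothing clears τ, a single EC is produced by a greedy
root-to-leaf argmax restricted to the observed child-of map, so every
protein receives at least one prediction. Decoding is monotone in τ before
the fallback, and every emitted code is prefix-consistent by construction.

## Training

Two phases under `L = λ₁ L_triplet + λ₂ L_BCE`, Adam (0.9, 0.999).

*Phase 1* (λ₂ = 0) trains only the extractor with the margin triplet loss.
An anchor and positive share at least one full EC number; the negative
shares none. Two choices matter and are ours:

- **Normalized triplet distance.** d is Euclidean on L2-normalized pooled
  features. On the unit sphere a fixed margin (default 1.0) is meaningful at
  any feature scale; on raw pooled features the hinge can be vacuously
  satisfied at initialization, in which case the phase provides no gradient
  at all.
- **Hard-negative-biased mining.** With probability 1/2 the negative is
  drawn from the deepest non-empty EC-prefix stratum around the anchor
  (same sub-subclass, then subclass, class, finally any disjoint enzyme).
  Uniformly drawn negatives are almost always trivially separated and
  contribute nothing to the hinge; prefix-stratified negatives are what
  pushes the extractor to separate sibling classes — empirically this is
  also what makes the attention maps concentrate on the planted
  functional-site windows, since siblings differ most strongly there.

*Phase 2* (λ₁ = 0, λ₂ = 1) freezes the extractor bit-exactly, computes every
protein's pooled features once, and trains the four MLPs on the cache with
the summed multi-level binary cross-entropy (probabilities clamped to
[1e-7, 1 − 1e-7]). The cache is what makes very large batches cheap; the
desk-scale profile nevertheless uses mini-batches (96) because a few hundred
proteins in a single batch would give too few optimizer steps. The published
large-scale schedule (batch 40 / 1000 epochs / lr 5e-4 constant, then batch
50 000 / 150 epochs / lr 1e-3 cosine-annealed) ships as the `paper` profile.

Both freeze contracts (phase 1 never touches the head, phase 2 never touches
the extractor) are exact and tested bit-for-bit. All randomness flows
through explicit seeded generators; runs are single-threaded and
deterministic.

## Synthetic data

The generator emulates the statistical skeleton the model assumes, so every
stage is testable offline:

- **Hierarchical prototypes.** Each label-tree node adds an increment of
  magnitude `separation × level_scales[k]` to its parent's prototype, so
  deeper distinctions are finer (default scales 1.0/0.7/0.5/0.4 on
  separation 3.0 against residue noise σ = 0.5).
- **Modality split.** Every increment has a common component (weight √ρ,
  seen by the 3Di stream through a fixed orthogonal map) and
  modality-private components (weight √(1−ρ)). At ρ = 1 the two streams are
  rotations of one latent signal; below 1 part of every class distinction
  lives in only one modality, so zeroing a stream genuinely discards signal
  — the regime in which single-modality ablations must lose accuracy.
- **Functional-site windows.** Each protein carries one contiguous motif
  window (default length 9) whose residues receive the leaf's level-4
  increment direction amplified by `motif_strength`: the serial-number
  identity is carried most strongly at the functional site, mirroring how
  catalytic-site residues determine the precise reaction while the global
  fold reflects the coarser classes. The window positions are exported as
  ground truth for attention-map evaluation.
- **Parent dependence.** Level-4 increment directions interpolate between
  parent-shared child directions (weight √parent_dependence) and
  leaf-private ones. At strength 1 a leaf is identifiable only as the
  conjunction "level-3 parent × shared child direction" — the regime in
  which conditioning the level-4 prediction on the level-3 prediction is
  informative, which is what the flat-head ablation tests.
- **Multi-label proteins.** With probability `multi_label_p` a protein
  receives a second leaf sharing its level-3 prefix (the PRDM9 pattern); its
  embeddings mix the two leaves' level-4 and motif signals so the second
  label is learnable rather than label noise.
- **Strings.** Amino-acid strings are uniform over the 20-letter alphabet;
  3Di strings follow the 3Di embedding rows through a fixed random
  projection, and `generate_3di_pair` produces reference/corrupted string
  pairs with a controlled substitution rate for recovery-rate statistics.

What the fixtures do *not* emulate: real embedding geometry (anisotropy,
length correlations, token-frequency effects), sequence-motif composition,
long-range structural contacts, and realistic label imbalance. Passing
tests therefore demonstrate correctness of the machinery and the designed
qualitative behaviours (hierarchy exploitation, modality fusion,
functional-site attention), not benchmark-transferable accuracy.

## Reference experiments

`scripts/acceptance.py --seed S --out results.json` recomputes, from
scratch: (1) held-out macro/micro and per-digit F1 plus motif-attention
means after full two-phase training on the separable reference fixture
(branching 3×2×2×2, 25 proteins/leaf, separation-to-noise 6, 480 train / 120
test proteins); (2) mean held-out level-4 F1 over 5 model seeds for the full
model, the flat-head variant and the sequence-only variant on a harder
parent-dependent fixture (branching 2×2×2×3, 10 proteins/leaf, ρ = 0.5,
parent dependence 1.0, σ = 1.6); and (3) the recovery-rate summary of 400
3Di string pairs corrupted at rate 0.2. Problem sizes are chosen so the
whole script runs in a few minutes on one CPU.

## Numerical conventions and limitations

- Double precision throughout; softmax is max-shifted; layer-norm ε = 1e-5;
  BCE clamp ε = 1e-7; the Euclidean distance adds 1e-12 inside the square
  root so the gradient exists at zero.
- Min-max normalization of attention importance maps all-equal scores
  (including L = 1 proteins) to zeros, by definition.
- Residue indices are 1-based inclusive in all reports, 0-based internally.
- Length mismatches between sequences, 3Di strings and embedding rows are
  errors, never truncations — a silent off-by-one would corrupt the
  residue-level attention maps.
- Checkpoints are single `.npz` files (versioned) holding all parameter
  arrays plus an embedded JSON with the architecture, label spaces and
  training configuration.
- The estimator follows scikit-learn conventions (get_params/set_params,
  clone, fitted `_` attributes) but its samples are variable-length matrix
  pairs, not a rectangular design matrix, so sklearn's generic
  cross-validation utilities do not apply directly.
- No GPU, no multi-threading, no mixed precision; the implementation
  targets correctness, determinism and desk-scale problem sizes, not
  throughput. Confidences are raw sigmoid chain-minima, not calibrated
  probabilities, and there is no non-enzyme rejection class.
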