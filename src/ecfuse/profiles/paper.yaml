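# Published large-scale training recipe: phase 1 batch 40 for 1000 epochs at a
# constant 5e-4; phase 2 batch 50 000 for 150 epochs at 1e-3 with cosine
# annealing; Adam (0.9, 0.999). Intended for full-scale data with pre-trained
# embedders, not for the bundled synthetic fixtures.
seed: 0
threshold: 0.5
model:
  n_heads: 2
  n_blocks: 3
  kernel_sizes: [7, 9, 11]
train:
  margin: 1.0
  triplets_per_epoch: 40
  phase1:
    epochs: 1000
    batch_size: 40
    lr: 0.0005
    cosine_annealing: false
  phase2:
    epochs: 150
    batch_size: 50000
    lr: 0.001
    cosine_annealing: true
synth:
  branching: [4, 3, 3, 3]
  proteins_per_leaf: 50
  length_range: [50, 120]
  n_features: 32
  separation: 3.0
  noise_sigma: 0.5
  rho: 0.75
  motif_len: 9
  motif_strength: 1.5
  multi_label_p: 0.1
  parent_dependence: 0.5
  level_scales: [1.0, 0.7, 0.5, 0.4]
  seed: 0
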