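# Desk-scale profile: trains in minutes on one CPU.
seed: 0
threshold: 0.5
model:
  n_heads: 2
  n_blocks: 3
  kernel_sizes: [7, 9, 11]
train:
  margin: 1.0
  triplets_per_epoch: 80
  phase1:
    epochs: 10
    batch_size: 40
    lr: 0.0005
    cosine_annealing: false
  phase2:
    epochs: 800
    batch_size: 96
    lr: 0.001
    cosine_annealing: true
synth:
  branching: [3, 2, 2, 2]
  proteins_per_leaf: 25
  length_range: [24, 40]
  n_features: 16
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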