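# Full-scale Monte Carlo study configuration: 1320 networks on 10 million
# simulated strokes with a 5 million-stroke test set.  This is a
# cluster-scale run (weeks of CPU time single-threaded); the desk-scale
# analogue lives in configs/default.yaml.  Cross-validation is omitted at
# this scale (split_fraction still controls the train/validation split for
# single-network runs).
dataset:
  n_train: 10000000
  n_test: 5000000
  seed: 0
  test_seed: 10000019
  split_fraction: 0.8
  duration: 0.02
architecture:
  widths: [10, 400, 400, 400, 16, 7]
  hidden_activation: arctan
training:
  optimizer: adam
  learning_rate: 1.0e-3
  batch_size: 128
  max_epochs: 1000
  min_delta: 0.01        # absolute minimum improvement per patience window
  patience: 1000         # batches
  eval_every: 100
pruning:
  sparsities: [0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.80, 0.85,
               0.90, 0.91, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97, 0.98]
  scope: global
ensemble:
  n_networks: 1320
  base_seed: 0
  threshold: 1.0e-3
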