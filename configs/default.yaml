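# Desk-scale run configuration (every field shown is also the built-in
# default).  Body parameters and sampling ranges are hawkmoth-scale
# stand-ins; see docs/methods.md.
body:
  m1: 1.1e-3      # head-thorax mass, kg
  m2: 0.9e-3      # abdomen mass, kg
  L1: 2.0e-2      # m
  L2: 2.5e-2      # m
  I1: 4.0e-8      # kg m^2
  I2: 5.0e-8      # kg m^2
  K: 1.0e-3       # torsional spring, N m / rad
  C: 1.0e-5       # torsional damper, N m s / rad
  beta0: 0.0      # rest angle phi - theta, rad (straight body)
  cd1: 5.0e-3     # linear drag, N s / m
  cd2: 5.0e-3
  g: 9.81
  rF: 0.0         # force acts at the joint
  drag_law: linear
  units: si
solver:
  method: RK45
  rtol: 1.0e-8
  atol: 1.0e-10
  report_dt: 1.0e-3
dataset:
  n_train: 50000
  n_test: 10000
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
  max_epochs: 50
  min_delta: 1.0e-5
  patience: 1000
  eval_every: 100
pruning:
  sparsities: [0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.80, 0.85,
               0.90, 0.91, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97, 0.98]
  scope: global
ensemble:
  n_networks: 12
  base_seed: 0
  threshold: 1.0e-3
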