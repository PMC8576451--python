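# Metabolic-flow family: mean-field fluid model, lifted 3 -> 96.
system: fluid
system_params:
  gamma: 0.1
  omega: 1.0
  A: -0.1
  lam: 10.0
  dt: 0.01
  T: 900
  init: zeta1       # (0, -0.01, 0); zeta2 = (0.01, -0.1, 0.5) is the
                    # high-complexity start
sigma: 0.0          # noise sweep grid: 0.001 0.005 0.010 0.050 0.100 0.500
n_ambient: 96
model:
  kind: ekatp
  L: 8
  hidden: [128, 64]
  activation: tanh
  loss_weights: {lambda_idy: 2.0, lambda_con: 2.0}
train:
  k: 8
  epochs: 100
  batch_size: 64
  lr: 0.003
  lr_schedule: cosine
  dtype: float32
  train_range: [0, 800]
protocol:
  horizon: 100
seed: 0
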