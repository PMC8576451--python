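# Oscillating protein-abundance family: nonlinear pendulum, lifted 2 -> 64.
system: pendulum
system_params:
  g_over_l: 1.0
  theta0: 0.8       # initial angle h; the study grid also uses 2.4
  theta_dot0: 0.0
  dt: 0.01
  T: 1600
sigma: 0.0          # the study grid also uses 0.03 and 0.08
n_ambient: 64
model:
  kind: ekatp       # the comparison harness also trains "kae"
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
  train_range: [0, 600]
protocol:
  horizon: 1000
  n_datasets: 5     # 20 in the full profile
seed: 0
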