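# Chaotic gene-expression family: discrete Lorenz-type map, lifted 3 -> 96.
# The "classic" variant keeps the trajectory on the attractor; the "printed"
# variant's x-update diverges under these parameters (the simulator raises
# an explicit divergence error if you select it here).
system: lorenz
system_params:
  eta: 10.0
  rho: 28.0
  beta: 2.6666666666666665
  h: 0.003          # nonlinearity level; the study grid also uses 0.006
  T: 1050
  init: [1.0, 1.0, 1.0]
  variant: classic
sigma: 0.0          # observation-noise std; the study grid also uses 0.01
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
  train_range: [0, 1000]
protocol:
  horizon: 50
seed: 0
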