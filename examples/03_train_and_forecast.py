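"""Train the EKATP on a lifted pendulum series and forecast the held-out tail.

A short desk-scale run: train on the first 600 of 1,600 steps, then roll
the linear latent dynamics 1,000 steps forward and decode.  Takes about
half a minute on one CPU.
"""

import numpy as np

from ekatp import (
    EKATPModel,
    EncoderSpec,
    LossWeights,
    PendulumParams,
    TrainConfig,
    lift,
    make_orthogonal_lift,
    predict,
    predictive_error,
    simulate_pendulum,
    train,
)

latent = simulate_pendulum(PendulumParams(theta0=0.8, T=1600))
lifting = make_orthogonal_lift(n=64, d=2, seed=0)
observed = lift(latent, lifting)

model = EKATPModel(
    EncoderSpec(input_dim=64, output_dim=8, hidden=(128, 64)),
    weights=LossWeights(lambda_idy=2.0, lambda_con=2.0),
    seed=0,
)
history = train(model, observed, TrainConfig(
    k=8, epochs=100, lr=3e-3, lr_schedule="cosine", dtype="float32",
    train_range=(0, 600), seed=0,
))
print(f"total loss: {history[0].total:.3e} (epoch 1) -> {history[-1].total:.3e} "
      f"(epoch {len(history)})")

forecast = predict(model, observed.values[:, 599], k=1000)
truth = observed.values[:, 600:1600]
curve = predictive_error(forecast, truth)
for step in (1, 100, 500, 1000):
    print(f"predictive error at step {step:5d}: {curve.error[step - 1]:.5f}")
# The error is the per-step MSE across the 64 ambient dimensions; values of
# a few 1e-3 at step 1,000 mean the forecast still tracks the oscillation
# phase a full period and a half past the training data.
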