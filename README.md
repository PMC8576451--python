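# ekatp

Forecasting high-dimensional nonlinear multi-omics time series with a
delay-embedding autoencoder whose latent dynamics are linear Koopman
operators in companion-matrix form.

## The problem and the model

Omics time courses — gene-expression panels, protein-abundance series,
metabolite profiles — are high-dimensional (n ~ 64–96 coordinates),
nonlinear, and noisy, yet they typically evolve on a low-dimensional
manifold. EKATP (Embedding-Koopman-Autoencoder Time-series Predictor)
exploits that structure with three coupled ingredients:

1. **Delay embedding.** An encoder χₑ maps each observation Fₜ ∈ ℝⁿ to a
   latent delay vector Yₜ = (yₜ, …, yₜ₊L₋₁)′ ∈ ℝᴸ, the classical
   delay-coordinate reconstruction of the underlying state; a decoder χ_d
   approximates its inverse (χ_d ∘ χₑ ≈ id).
2. **Companion Koopman operators.** Latent time evolution is linear in both
   directions: Yₜ₊₁ = C Yₜ and Yₜ₋₁ = D Yₜ, where C is a companion matrix
   (pure shift plus one trainable row a, a₁ ≠ 0) and D its backward mirror
   (trainable first row b, b_L ≠ 0). Only 2L dynamical parameters are
   learned; the shift structure is exact by construction.
3. **A five-term objective.** Training minimizes
   L = λ_id·L_id + λ_fwd·L_fwd + λ_bwd·L_bwd + λ_idy·L_idy + λ_con·L_con,
   combining reconstruction, k-step forward and backward rollout error in
   the ambient space, latent linearity (Cˢχₑ(Fₜ) ≈ χₑ(Fₜ₊ₛ) and the
   backward analogue), and forward/backward consistency
   (χ_d(DˢCˢYₜ) ≈ Fₜ ≈ χ_d(CˢDˢYₜ)). All norms are per-element MSE.

Forecasts roll the latent dynamics: F̂ₜ₊ₖ = χ_d(Cᵏ χₑ(Fₜ)), in either time
direction. The **KAE** ablation keeps the same autoencoder but uses one
dense unstructured forward operator (L² parameters) and drops the backward
and consistency terms — the baseline the structured model is measured
against.

No external data are needed: three synthetic generators emulate the omics
behaviours (a discrete Lorenz-type map for chaotic gene regulation, a
nonlinear pendulum for oscillating protein abundance, a mean-field fluid
model for metabolic flow), optionally corrupted by white Gaussian noise of
intensity σ and lifted to ℝⁿ by a random orthogonal map P (F = PV, with
P′P = I so the mapping is exactly reversible).

## Worked example

```bash
python examples/03_train_and_forecast.py
```

trains the EKATP on the first 600 steps of a 64-dimensional lifted
pendulum series (amplitude h = 0.8, no noise) and forecasts the remaining
1,000 steps from the last training state. Output from that run:

```
total loss: 7.238e+00 (epoch 1) -> 6.126e-03 (epoch 100)
predictive error at step     1: 0.00000
predictive error at step   100: 0.00186
predictive error at step   500: 0.01275
predictive error at step  1000: 0.00689
```

The predictive error is the per-step MSE across the 64 ambient
dimensions. Staying at a few 10⁻³ through step 1,000 means the linear
latent rollout still tracks the oscillation phase a period and a half
beyond the training data; a forecast that lost phase entirely would sit
an order of magnitude higher (≈ 2·Var of the signal) on this series.

Other entry points: `examples/01_simulate_and_lift.py` (generators, noise,
orthogonal lift and its exact inverse), `examples/02_companion_operators.py`
(operator structure, spectrum, least-squares coefficient recovery),
`examples/04_noise_robustness.py` (PCC/RMSE under growing σ), and a thin
CLI — `ekatp simulate|train|predict|evaluate|reproduce` — over the same
API (YAML configs under `configs/`). `ekatp reproduce proteomics --out dir/`
re-runs a whole experiment family; `--profile smoke` finishes each family
in about a minute.

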