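"""The EKATP network: delay-embedding autoencoder with companion Koopman dynamics.

An encoder chi_e maps each high-dimensional observation F_t to a latent
delay vector Y_t of dimension L; a decoder chi_d maps back.  Latent time
evolution is linear: Y_{t+1} = C Y_t (forward) and Y_{t-1} = D Y_t
(backward), with C and D structured companion matrices whose only
trainable parts are the coefficient vectors a and b.  Training minimizes
a weighted sum of five mean-square losses:

* reconstruction    L_id  = ||chi_d(chi_e(F_t)) - F_t||
* forward rollout   L_fwd = (1/k) sum_s ||chi_d(C^s Y_t) - F_{t+s}||
* backward rollout  L_bwd = (1/k) sum_s ||chi_d(D^s Y_t) - F_{t-s}||
* latent linearity  L_idy = (1/k) sum_s ||C^s Y_t - chi_e(F_{t+s})|| + ||D^s Y_t - chi_e(F_{t-s})||
* consistency       L_con = (1/k) sum_s ||chi_d(D^s C^s Y_t) - F_t|| + ||chi_d(C^s D^s Y_t) - F_t||

All norms are per-element mean squared errors.  The KAE ablation keeps the
same autoencoder but replaces the structured pair (C, D) with one dense
unstructured forward operator and drops the backward and consistency terms.

Everything here is plain numpy; gradients come from the package's own
reverse-mode engine (:mod:`ekatp._autodiff`) and are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .koopman import CompanionBackward, CompanionForward, apply_backward, apply_forward
from .simulators import LiftedTrajectory, LatentTrajectory

__all__ = [
    "EncoderSpec",
    "DecoderSpec",
    "LossWeights",
    "TrainConfig",
    "LossReport",
    "EKATPModel",
    "KAEModel",
    "loss_id",
    "loss_fwd",
    "loss_bwd",
    "loss_idy",
    "loss_con",
    "total_loss",
    "train",
    "predict",
    "make_kae",
    "TrainingDivergedError",
    "ConstraintViolationError",
]

_ACTIVATIONS = {"tanh": ad.tanh, "relu": ad.relu, "identity": lambda x: x}


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""


class ConstraintViolationError(RuntimeError):
    """A companion constraint (a1 != 0 or bL != 0) was violated during training."""


# ---------------------------------------------------------------------------
# specs and configs


@dataclass(frozen=True)
class EncoderSpec:
    input_dim: int
    output_dim: int
    hidden: tuple[int, ...] = (128, 64)
    activation: str = "tanh"

    def __post_init__(self):
        if self.output_dim < 2:
            raise ValueError("latent dimension must be >= 2")
        if len(self.hidden) < 1:
            raise ValueError("need at least one hidden layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class DecoderSpec:
    input_dim: int
    output_dim: int
    hidden: tuple[int, ...] = (64, 128)
    activation: str = "tanh"

    @classmethod
    def mirror(cls, enc: EncoderSpec) -> "DecoderSpec":
        return cls(enc.output_dim, enc.input_dim, tuple(reversed(enc.hidden)), enc.activation)

    def __post_init__(self):
        if len(self.hidden) < 1:
            raise ValueError("need at least one hidden layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class LossWeights:
    lambda_id: float = 1.0
    lambda_fwd: float = 1.0
    lambda_bwd: float = 1.0
    lambda_idy: float = 1.0
    lambda_con: float = 1.0

    def __post_init__(self):
        vals = (self.lambda_id, self.lambda_fwd, self.lambda_bwd,
                self.lambda_idy, self.lambda_con)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``train_range`` is the half-open [start, stop) slice of trajectory
    columns used for training; windows are sampled with stride 1 and any
    window needing an index outside the slice is dropped.  ``normalize``
    standardizes the training segment (per-dimension mean, one global
    scale) before it reaches the network; predictions are mapped back.
    """

    k: int = 8
    epochs: int = 300
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    train_range: tuple[int, int] = (0, 600)
    normalize: bool = True
    constraint_mode: Literal["clamp", "abort"] = "clamp"
    dtype: Literal["float64", "float32"] = "float64"
    lr_schedule: Literal["constant", "cosine"] = "constant"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.train_range[1] <= self.train_range[0]:
            raise ValueError("empty training range")


@dataclass
class LossReport:
    l_id: float
    l_fwd: float
    l_bwd: float
    l_idy: float
    l_con: float
    total: float


# ---------------------------------------------------------------------------
# multilayer perceptron


class MLP:
    """Fully connected network with Gaussian fan-in initialization."""

    def __init__(self, dims: Sequence[int], activation: str, rng: np.random.Generator):
        self.activation = activation
        self.layers: list[tuple[Tensor, Tensor]] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            w = rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in)
            self.layers.append(
                (Tensor(w, requires_grad=True), Tensor(np.zeros(fan_out), requires_grad=True))
            )

    def __call__(self, x: Tensor) -> Tensor:
        act = _ACTIVATIONS[self.activation]
        h = x
        for i, (w, b) in enumerate(self.layers):
            h = h @ w + b
            if i < len(self.layers) - 1:  # linear output layer
                h = act(h)
        return h

    @property
    def params(self) -> list[Tensor]:
        return [t for pair in self.layers for t in pair]


# ---------------------------------------------------------------------------
# models


class EKATPModel:
    """Encoder, decoder and the structured companion operator pair."""

    def __init__(
        self,
        encoder_spec: EncoderSpec,
        decoder_spec: DecoderSpec | None = None,
        weights: LossWeights = LossWeights(),
        seed: int = 0,
        shift_eps: float = 1e-2,
    ):
        if decoder_spec is None:
            decoder_spec = DecoderSpec.mirror(encoder_spec)
        if encoder_spec.output_dim != decoder_spec.input_dim:
            raise ValueError("encoder output dim must equal decoder input dim")
        if encoder_spec.input_dim != decoder_spec.output_dim:
            raise ValueError("decoder must map back to the ambient dimension")
        self.encoder_spec = encoder_spec
        self.decoder_spec = decoder_spec
        self.weights = weights
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = MLP(
            (encoder_spec.input_dim, *encoder_spec.hidden, encoder_spec.output_dim),
            encoder_spec.activation, rng,
        )
        self.decoder = MLP(
            (decoder_spec.input_dim, *decoder_spec.hidden, decoder_spec.output_dim),
            decoder_spec.activation, rng,
        )
        L = encoder_spec.output_dim
        # near-shift prior honoring a1 != 0 and bL != 0
        a0 = np.zeros(L); a0[0] = shift_eps; a0[-1] = 1.0
        b0 = np.zeros(L); b0[0] = 1.0; b0[-1] = shift_eps
        self.a = Tensor(a0, requires_grad=True)
        self.b = Tensor(b0, requires_grad=True)
        self.mu = np.zeros(encoder_spec.input_dim)
        self.scale = 1.0
        self.trained = False

    # -- dims --------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.encoder_spec.input_dim

    @property
    def L(self) -> int:
        return self.encoder_spec.output_dim

    @property
    def params(self) -> list[Tensor]:
        return self.encoder.params + self.decoder.params + [self.a, self.b]

    # -- latent dynamics ---------------------------------------------------

    def _step_fwd(self, Y: Tensor) -> Tensor:
        return ad.concat([Y[:, 1:], (Y @ self.a).reshape(-1, 1)], axis=1)

    def _step_bwd(self, Y: Tensor) -> Tensor:
        return ad.concat([(Y @ self.b).reshape(-1, 1), Y[:, :-1]], axis=1)

    _CONSTRAINT_FLOOR = 1e-6

    def _check_constraints(self, mode: str = "clamp") -> None:
        """Keep a1 != 0 and bL != 0 after each epoch.

        ``clamp`` projects the offending coefficient back to the floor
        magnitude (training may legitimately shrink the oldest delay
        coefficient toward zero); ``abort`` raises instead.
        """
        floor = self._CONSTRAINT_FLOOR
        bad = [name for name, v in (("a1", self.a.data[0]), ("bL", self.b.data[-1]))
               if abs(v) <= floor]
        if not bad:
            return
        if mode == "abort":
            raise ConstraintViolationError(
                f"companion constraints violated: a1={self.a.data[0]:.3e}, "
                f"bL={self.b.data[-1]:.3e}"
            )
        if abs(self.a.data[0]) <= floor:
            self.a.data[0] = floor if self.a.data[0] >= 0 else -floor
        if abs(self.b.data[-1]) <= floor:
            self.b.data[-1] = floor if self.b.data[-1] >= 0 else -floor

    def operators(self) -> tuple[CompanionForward, CompanionBackward]:
        return CompanionForward(self.a.data.copy()), CompanionBackward(self.b.data.copy())

    def _step_np(self, y: np.ndarray, direction: str) -> np.ndarray:
        fwd, bwd = self.operators()
        if direction == "forward":
            return apply_forward(fwd, y).y
        return apply_backward(bwd, y).y

    # -- encode / decode ---------------------------------------------------

    def _normalize(self, F: np.ndarray) -> np.ndarray:
        return (F - self.mu[:, None]) / self.scale

    def encode(self, F: np.ndarray) -> np.ndarray:
        """Map ambient states (n,) or (n, T) to latent delay vectors."""
        F = np.asarray(F, dtype=float)
        if not np.isfinite(F).all():
            raise ValueError("encode received non-finite input")
        single = F.ndim == 1
        cols = F[:, None] if single else F
        if cols.shape[0] != self.n:
            raise ValueError(f"expected ambient dimension {self.n}, got {cols.shape[0]}")
        x = Tensor(self._normalize(cols).T)
        y = self.encoder(x).data.T
        return y[:, 0] if single else y

    def decode(self, Y: np.ndarray) -> np.ndarray:
        """Map latent vectors (L,) or (L, T) back to ambient states."""
        Y = np.asarray(Y, dtype=float)
        single = Y.ndim == 1
        cols = Y[:, None] if single else Y
        if cols.shape[0] != self.L:
            raise ValueError(f"expected latent dimension {self.L}, got {cols.shape[0]}")
        out = self.decoder(Tensor(cols.T)).data.T * self.scale + self.mu[:, None]
        return out[:, 0] if single else out

    # -- losses on a batch of windows -------------------------------------

    def _batch_losses(self, W: np.ndarray, k: int) -> dict[str, Tensor]:
        """Loss tensors for normalized windows W of shape (B, 2k+1, n)."""
        B, width, n = W.shape
        assert width == 2 * k + 1
        X = Tensor(W.reshape(B * width, n))
        Yall = self.encoder(X).reshape(B, width, self.L)
        Yc = Yall[:, k, :]
        Fc = Tensor(W[:, k, :])

        losses: dict[str, Tensor] = {}
        losses["l_id"] = ad.mse(self.decoder(Yc), Fc)

        fwd_states, bwd_states = [], []
        acc_f = acc_b = acc_i = acc_c = None

        Yf, Yb = Yc, Yc
        for s in range(1, k + 1):
            Yf = self._step_fwd(Yf)
            fwd_states.append(Yf)
            t_f = ad.mse(self.decoder(Yf), Tensor(W[:, k + s, :]))
            acc_f = t_f if acc_f is None else acc_f + t_f
            i_f = ad.mse(Yf, Yall[:, k + s, :])
            acc_i = i_f if acc_i is None else acc_i + i_f
            if self._has_backward:
                Yb = self._step_bwd(Yb)
                bwd_states.append(Yb)
                t_b = ad.mse(self.decoder(Yb), Tensor(W[:, k - s, :]))
                acc_b = t_b if acc_b is None else acc_b + t_b
                acc_i = acc_i + ad.mse(Yb, Yall[:, k - s, :])

        losses["l_fwd"] = acc_f * (1.0 / k)
        losses["l_idy"] = acc_i * (1.0 / k)
        if self._has_backward:
            losses["l_bwd"] = acc_b * (1.0 / k)
            for s in range(1, k + 1):
                u = fwd_states[s - 1]
                for _ in range(s):
                    u = self._step_bwd(u)
                v = bwd_states[s - 1]
                for _ in range(s):
                    v = self._step_fwd(v)
                t_c = ad.mse(self.decoder(u), Fc) + ad.mse(self.decoder(v), Fc)
                acc_c = t_c if acc_c is None else acc_c + t_c
            losses["l_con"] = acc_c * (1.0 / k)
        else:
            losses["l_bwd"] = Tensor(0.0)
            losses["l_con"] = Tensor(0.0)
        return losses

    _has_backward = True

    def _weighted_total(self, losses: dict[str, Tensor]) -> Tensor:
        w = self.weights
        return (losses["l_id"] * w.lambda_id + losses["l_fwd"] * w.lambda_fwd
                + losses["l_bwd"] * w.lambda_bwd + losses["l_idy"] * w.lambda_idy
                + losses["l_con"] * w.lambda_con)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        blob = {
            "kind": type(self).__name__,
            "encoder_spec": asdict(self.encoder_spec),
            "decoder_spec": asdict(self.decoder_spec),
            "weights": asdict(self.weights),
            "seed": self.seed,
            "mu": self.mu.tolist(),
            "scale": float(self.scale),
            "trained": self.trained,
            "operators": {"L": self.L, "a": self.a.data.tolist(), "b": self.b.data.tolist()},
            "encoder_layers": [[w.data.tolist(), b.data.tolist()] for w, b in self.encoder.layers],
            "decoder_layers": [[w.data.tolist(), b.data.tolist()] for w, b in self.decoder.layers],
        }
        if type(self).__name__ == "KAEModel":
            blob["operators"] = {"L": self.L, "K": self.K.data.tolist()}
        Path(path).write_text(json.dumps(blob))

    @staticmethod
    def load(path: str | Path) -> "EKATPModel":
        blob = json.loads(Path(path).read_text())
        enc = EncoderSpec(**{**blob["encoder_spec"],
                             "hidden": tuple(blob["encoder_spec"]["hidden"])})
        dec = DecoderSpec(**{**blob["decoder_spec"],
                             "hidden": tuple(blob["decoder_spec"]["hidden"])})
        cls = KAEModel if blob["kind"] == "KAEModel" else EKATPModel
        model = cls(enc, dec, LossWeights(**blob["weights"]), seed=blob["seed"])
        for (w, b), (wd, bd) in zip(model.encoder.layers, blob["encoder_layers"]):
            w.data = np.asarray(wd); b.data = np.asarray(bd)
        for (w, b), (wd, bd) in zip(model.decoder.layers, blob["decoder_layers"]):
            w.data = np.asarray(wd); b.data = np.asarray(bd)
        if blob["kind"] == "KAEModel":
            model.K.data = np.asarray(blob["operators"]["K"])
        else:
            model.a.data = np.asarray(blob["operators"]["a"])
            model.b.data = np.asarray(blob["operators"]["b"])
        model.mu = np.asarray(blob["mu"])
        model.scale = blob["scale"]
        model.trained = blob["trained"]
        return model


class KAEModel(EKATPModel):
    """Koopman-autoencoder ablation: one dense forward operator, no backward
    or consistency terms.  The operator has L^2 trainable entries against the
    structured model's L."""

    _has_backward = False

    def __init__(self, encoder_spec, decoder_spec=None,
                 weights: LossWeights = LossWeights(), seed: int = 0,
                 shift_eps: float = 1e-2):
        super().__init__(encoder_spec, decoder_spec, weights, seed, shift_eps)
        weights = LossWeights(weights.lambda_id, weights.lambda_fwd, 0.0,
                              weights.lambda_idy, 0.0)
        self.weights = weights
        L = self.L
        # standard dense-layer init: the near-shift prior is part of the
        # structured-operator contribution being ablated, so the dense
        # operator starts like any linear layer
        rng = np.random.default_rng(seed + 1)
        self.K = Tensor(rng.standard_normal((L, L)) / np.sqrt(L), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return self.encoder.params + self.decoder.params + [self.K]

    def _step_fwd(self, Y: Tensor) -> Tensor:
        return _matmul_t(Y, self.K)

    def _step_np(self, y: np.ndarray, direction: str) -> np.ndarray:
        if direction != "forward":
            raise ValueError("the KAE ablation has no backward operator")
        return self.K.data @ y

    def _check_constraints(self, mode: str = "clamp") -> None:
        pass  # unconstrained dense operator

    def operators(self):
        raise NotImplementedError("KAE uses a dense operator; see model.K")


def _matmul_t(Y: Tensor, K: Tensor) -> Tensor:
    """Y K' for batched rows Y (B, L): one dense latent step."""
    out = Tensor(Y.data @ K.data.T, _parents=(Y, K))

    def backward(grad):
        if Y.requires_grad:
            Y._accumulate(grad @ K.data)
        if K.requires_grad:
            K._accumulate(grad.T @ Y.data)

    out._backward = backward
    return out


def make_kae(encoder_spec: EncoderSpec, decoder_spec: DecoderSpec | None = None,
             weights: LossWeights = LossWeights(), seed: int = 0) -> KAEModel:
    """Build the KAE ablation model (dense forward operator, forward losses only)."""
    return KAEModel(encoder_spec, decoder_spec, weights, seed=seed)


# ---------------------------------------------------------------------------
# standalone loss functions


def loss_id(F_hat: np.ndarray, F: np.ndarray) -> float:
    """Reconstruction loss: per-element mean squared error."""
    F_hat = np.asarray(F_hat, dtype=float)
    F = np.asarray(F, dtype=float)
    if F_hat.shape != F.shape:
        raise ValueError(f"shape mismatch: {F_hat.shape} vs {F.shape}")
    return float(np.mean((F_hat - F) ** 2))


def _window_losses(model: EKATPModel, window: np.ndarray, k: int) -> dict[str, float]:
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != model.n:
        raise ValueError(f"window must be (n={model.n}, >=2k+1)")
    if window.shape[1] < 2 * k + 1:
        raise ValueError(f"window of width {window.shape[1]} is shorter than 2k+1={2 * k + 1}")
    mid = window.shape[1] // 2
    cols = window[:, mid - k: mid + k + 1]
    W = model._normalize(cols).T[None, :, :]
    losses = model._batch_losses(W, k)
    return {name: float(t.data) for name, t in losses.items()}


def loss_fwd(model: EKATPModel, window: np.ndarray, k: int) -> float:
    """Forward k-step rollout loss on one window F_{t-k} ... F_{t+k}."""
    return _window_losses(model, window, k)["l_fwd"]


def loss_bwd(model: EKATPModel, window: np.ndarray, k: int) -> float:
    """Backward k-step rollout loss on one window."""
    return _window_losses(model, window, k)["l_bwd"]


def loss_idy(model: EKATPModel, window: np.ndarray, k: int) -> float:
    """Latent-linearity loss on one window."""
    return _window_losses(model, window, k)["l_idy"]


def loss_con(model: EKATPModel, window: np.ndarray, k: int) -> float:
    """Forward/backward consistency loss on one window."""
    return _window_losses(model, window, k)["l_con"]


def total_loss(report: LossReport, w: LossWeights) -> float:
    """Weighted composite objective."""
    return (w.lambda_id * report.l_id + w.lambda_fwd * report.l_fwd
            + w.lambda_bwd * report.l_bwd + w.lambda_idy * report.l_idy
            + w.lambda_con * report.l_con)


# ---------------------------------------------------------------------------
# optimization


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train(
    model: EKATPModel,
    data: LiftedTrajectory | LatentTrajectory | np.ndarray,
    cfg: TrainConfig,
) -> list[LossReport]:
    """Fit the model on sliding windows of the training segment.

    Returns the per-epoch loss history.  Windows of width 2k+1 are taken
    with stride 1 from ``cfg.train_range``; windows that would need indices
    outside the segment are dropped.  Deterministic under a fixed
    ``cfg.seed`` (which also drives the batch shuffling).
    """
    F = data if isinstance(data, np.ndarray) else data.values
    t0, t1 = cfg.train_range
    if not (0 <= t0 < t1 <= F.shape[1]):
        raise ValueError(f"train_range {cfg.train_range} outside trajectory of length {F.shape[1]}")
    seg = F[:, t0:t1]
    k = cfg.k
    if seg.shape[1] < 2 * k + 2:
        raise ValueError(f"training segment of length {seg.shape[1]} is shorter than 2k+2")
    if cfg.normalize:
        model.mu = seg.mean(axis=1)
        centered = seg - model.mu[:, None]
        model.scale = float(centered.std()) or 1.0
    dtype = np.dtype(cfg.dtype)
    for p in model.params:
        p.data = p.data.astype(dtype)
    segn = model._normalize(seg).astype(dtype)

    width = 2 * k + 1
    windows = np.lib.stride_tricks.sliding_window_view(segn.T, width, axis=0)
    windows = np.ascontiguousarray(windows.transpose(0, 2, 1))  # (num, 2k+1, n)
    num = windows.shape[0]

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.lr)
    history: list[LossReport] = []
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":  # anneal to ~3% of the base rate
            frac = epoch / max(cfg.epochs - 1, 1)
            opt.lr = cfg.lr * (0.03 + 0.97 * 0.5 * (1 + np.cos(np.pi * frac)))
        order = rng.permutation(num)
        sums = {name: 0.0 for name in ("l_id", "l_fwd", "l_bwd", "l_idy", "l_con")}
        seen = 0
        for lo in range(0, num, cfg.batch_size):
            batch = windows[order[lo: lo + cfg.batch_size]]
            losses = model._batch_losses(batch, k)
            total = model._weighted_total(losses)
            if not np.isfinite(total.data):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {len(history)}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            for name in sums:
                sums[name] += float(losses[name].data) * batch.shape[0]
            seen += batch.shape[0]
        avg = {name: s / seen for name, s in sums.items()}
        report = LossReport(**avg, total=0.0)
        report.total = total_loss(report, model.weights)
        history.append(report)
        model._check_constraints(cfg.constraint_mode)
    for p in model.params:  # hand back float64 weights regardless of training dtype
        p.data = p.data.astype(np.float64)
    model.trained = True
    return history


def predict(
    model: EKATPModel,
    F_t: np.ndarray,
    k: int,
    direction: Literal["forward", "backward"] = "forward",
) -> np.ndarray:
    """Roll the latent dynamics k steps from F_t and decode each step.

    Returns an (n, k) block of predictions for s = 1..k; with k = 0 the
    single reconstructed column decode(encode(F_t)) is returned.
    """
    if not model.trained:
        warnings.warn("predicting with an untrained model", stacklevel=2)
    if k < 0:
        raise ValueError("k must be non-negative")
    y = model.encode(np.asarray(F_t, dtype=float))
    if k == 0:
        return model.decode(y)[:, None]
    states = np.empty((model.L, k))
    for s in range(k):
        y = model._step_np(y, direction)
        states[:, s] = y
    return model.decode(states)
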