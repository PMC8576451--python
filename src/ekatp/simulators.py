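"""Synthetic multi-omics time-series generators.

Three low-dimensional dynamical systems stand in for the behaviours seen in
omics time courses: a discrete Lorenz-type map (chaotic gene-expression
dynamics), a nonlinear pendulum (oscillating protein abundances), and a
mean-field fluid model (metabolic flow).  Trajectories may be corrupted by
additive white Gaussian observation noise and are lifted to a
high-dimensional ambient space by a random orthogonal map, so the observed
series lives on a low-dimensional manifold — the structure the EKATP model
is designed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "DivergenceError",
    "LorenzParams",
    "PendulumParams",
    "FluidParams",
    "NoiseSpec",
    "LatentTrajectory",
    "LiftingMap",
    "LiftedTrajectory",
    "simulate_lorenz",
    "simulate_pendulum",
    "simulate_fluid",
    "add_noise",
    "make_orthogonal_lift",
    "lift",
    "project",
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "FLUID_INIT_LOW",
    "FLUID_INIT_HIGH",
]

#: Initial conditions of the fluid system giving low / high nonlinear
#: complexity (named zeta1 / zeta2 in the source model).
FLUID_INIT_LOW = (0.0, -0.01, 0.0)
FLUID_INIT_HIGH = (0.01, -0.1, 0.5)

_DIVERGENCE_LIMIT = 1e8


class DivergenceError(RuntimeError):
    """A simulated trajectory left the representable range."""

    def __init__(self, system: str, step: int):
        self.system = system
        self.step = step
        super().__init__(
            f"{system} trajectory diverged (non-finite or |state| > "
            f"{_DIVERGENCE_LIMIT:g}) at step {step}"
        )


# ---------------------------------------------------------------------------
# parameter types


@dataclass(frozen=True)
class LorenzParams:
    """Discrete Lorenz-type map for chaotic gene-regulatory dynamics.

    ``h`` is the discrete step size and doubles as the nonlinearity level:
    larger ``h`` makes the inter-gene coupling more complicated.  The
    ``variant`` switch selects the x-update: ``"printed"`` uses
    x_{t+1} = x_t + h*eta*(y_t - z_t); ``"classic"`` uses the textbook
    Lorenz form x_{t+1} = x_t + h*eta*(y_t - x_t).
    """

    eta: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    h: float = 0.003
    T: int = 1050
    init: tuple[float, float, float] = (1.0, 1.0, 1.0)
    variant: Literal["printed", "classic"] = "printed"

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.T < 2:
            raise ValueError("T must be at least 2")
        if self.variant not in ("printed", "classic"):
            raise ValueError(f"unknown lorenz variant {self.variant!r}")


@dataclass(frozen=True)
class PendulumParams:
    """Nonlinear pendulum for oscillating proteomic dynamics.

    ``theta0`` (the initial angle, radians) sets the oscillation amplitude
    and hence the degree of nonlinearity.
    """

    g_over_l: float = 1.0
    theta0: float = 0.8
    theta_dot0: float = 0.0
    dt: float = 0.01
    T: int = 1600

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 2:
            raise ValueError("T must be at least 2")


@dataclass(frozen=True)
class FluidParams:
    """Mean-field fluid model for metabolic flow dynamics.

    The cubic system couples an oscillatory (x, y) pair to a shift mode z
    attracted to the paraboloid z = x^2 + y^2 at rate ``lam``.
    """

    gamma: float = 0.1
    omega: float = 1.0
    A: float = -0.1
    lam: float = 10.0
    dt: float = 0.01
    T: int = 900
    init: tuple[float, float, float] = FLUID_INIT_LOW

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 2:
            raise ValueError("T must be at least 2")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian observation noise of standard deviation sigma."""

    sigma: float
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# trajectory containers


@dataclass
class LatentTrajectory:
    """Low-dimensional state sequence V, stored as a (d, T) array."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a (d, T) matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("trajectory contains NaN or Inf")

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def time_index(self) -> np.ndarray:
        return np.arange(self.T)


@dataclass
class LiftingMap:
    """Random orthogonal lift P (n x d, orthonormal columns)."""

    P: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] <= self.P.shape[1]:
            raise ValueError("P must be n x d with n > d")
        gram = self.P.T @ self.P
        if np.abs(gram - np.eye(self.d)).max() > 1e-10:
            raise ValueError("columns of P are not orthonormal")

    @property
    def n(self) -> int:
        return self.P.shape[0]

    @property
    def d(self) -> int:
        return self.P.shape[1]


@dataclass
class LiftedTrajectory:
    """High-dimensional observed sequence F = P V, stored as (n, T)."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be an (n, T) matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("trajectory contains NaN or Inf")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# simulators


def _check_step(state: np.ndarray, system: str, step: int) -> None:
    if not np.isfinite(state).all() or np.abs(state).max() > _DIVERGENCE_LIMIT:
        raise DivergenceError(system, step)


def simulate_lorenz(params: LorenzParams) -> LatentTrajectory:
    """Iterate the discrete Lorenz-type map for ``params.T`` steps."""
    eta, rho, beta, h = params.eta, params.rho, params.beta, params.h
    v = np.empty((3, params.T))
    v[:, 0] = params.init
    for t in range(params.T - 1):
        x, y, z = v[:, t]
        if params.variant == "printed":
            dx = eta * (y - z)
        else:
            dx = eta * (y - x)
        v[0, t + 1] = x + h * dx
        v[1, t + 1] = y + h * (x * (rho - z) - y)
        v[2, t + 1] = z + h * (x * y - beta * z)
        _check_step(v[:, t + 1], "lorenz", t + 1)
    return LatentTrajectory(v)


def _rk4(f, y0: np.ndarray, dt: float, T: int, system: str) -> np.ndarray:
    out = np.empty((y0.size, T))
    out[:, 0] = y0
    y = y0.astype(float)
    for t in range(T - 1):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        _check_step(y, system, t + 1)
        out[:, t + 1] = y
    return out


def simulate_pendulum(params: PendulumParams) -> LatentTrajectory:
    """Integrate theta'' + (g/l) sin(theta) = 0 with fixed-step RK4.

    Returns the (theta, theta_dot) pair as a 2 x T trajectory.
    """
    gl = params.g_over_l

    def f(s):
        return np.array([s[1], -gl * np.sin(s[0])])

    y0 = np.array([params.theta0, params.theta_dot0])
    return LatentTrajectory(_rk4(f, y0, params.dt, params.T, "pendulum"))


def simulate_fluid(params: FluidParams) -> LatentTrajectory:
    """Integrate the three coupled mean-field fluid ODEs with RK4."""
    g, w, A, lam = params.gamma, params.omega, params.A, params.lam

    def f(s):
        x, y, z = s
        return np.array(
            [g * x - w * y + A * x * z, w * x + g * y + A * y * z, -lam * (z - x * x - y * y)]
        )

    y0 = np.asarray(params.init, dtype=float)
    return LatentTrajectory(_rk4(f, y0, params.dt, params.T, "fluid"))


# ---------------------------------------------------------------------------
# noise and lifting


def add_noise(traj: LatentTrajectory, noise: NoiseSpec) -> LatentTrajectory:
    """Perturb every entry by an independent N(0, sigma^2) draw."""
    if noise.sigma == 0:
        return LatentTrajectory(traj.values.copy())
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.sigma, size=traj.values.shape)
    return LatentTrajectory(traj.values + eps)


def make_orthogonal_lift(n: int, d: int, seed: int = 0) -> LiftingMap:
    """Draw a random n x d matrix with orthonormal columns.

    A standard-Gaussian matrix is orthonormalized by thin QR; signs are
    fixed so diag(R) > 0, making the draw a deterministic function of the
    seed.
    """
    if n <= d or d < 1:
        raise ValueError(f"need n > d >= 1, got n={n}, d={d}")
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n, d)))
    q = q * np.sign(np.diag(r))
    return LiftingMap(q, seed=seed)


def lift(traj: LatentTrajectory, lifting: LiftingMap) -> LiftedTrajectory:
    """Map a latent trajectory to the ambient space: F = P V."""
    if lifting.d != traj.d:
        raise ValueError(f"lifting map expects d={lifting.d}, trajectory has d={traj.d}")
    return LiftedTrajectory(
        lifting.P @ traj.values,
        provenance={"lift_seed": lifting.seed, "d": traj.d, "n": lifting.n},
    )


def project(traj: LiftedTrajectory | LatentTrajectory, lifting: LiftingMap) -> LatentTrajectory:
    """Map an ambient trajectory back to latent coordinates: V = P' F."""
    if lifting.n != traj.values.shape[0]:
        raise ValueError(
            f"lifting map expects n={lifting.n}, trajectory has n={traj.values.shape[0]}"
        )
    return LatentTrajectory(lifting.P.T @ traj.values)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_trajectory_tsv(traj: LatentTrajectory | LiftedTrajectory, path: str | Path) -> None:
    """Write a trajectory as TSV: header ``t s1 ... sd``, one row per step."""
    d = traj.values.shape[0]
    frame = pd.DataFrame(traj.values.T, columns=[f"s{i + 1}" for i in range(d)])
    frame.insert(0, "t", np.arange(traj.values.shape[1]))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory_tsv(path: str | Path) -> LatentTrajectory:
    """Read a trajectory written by :func:`write_trajectory_tsv` (or any
    delimited file with a leading step column)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = [c for c in frame.columns if c != "t"]
    return LatentTrajectory(frame[cols].to_numpy().T)
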