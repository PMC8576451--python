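"""Structured companion-matrix Koopman operators.

The latent state is a delay vector Y_t = (y_t, ..., y_{t+L-1})'.  One step
forward in time is a shift: the first L-1 entries of Y_{t+1} are the last
L-1 entries of Y_t, and only the new final entry must be predicted, as a
linear combination a'Y_t.  The forward operator C is therefore a companion
matrix whose only trainable row is the last one (coefficients a, a1 != 0);
the backward operator D mirrors this with a trainable first row
(coefficients b, bL != 0).  Applications are implemented as
shift-plus-dot-product so the structural zeros and ones are exact;
:func:`materialize` builds the dense matrix for tests and diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LatentState",
    "CompanionForward",
    "CompanionBackward",
    "apply_forward",
    "apply_backward",
    "k_step",
    "materialize",
    "inverse_companion",
    "fit_companion_lsq",
    "SingularFitError",
    "operators_to_json",
    "operators_from_json",
]


class SingularFitError(np.linalg.LinAlgError):
    """Least-squares companion fit is rank deficient."""


@dataclass
class LatentState:
    """Delay-coordinate latent state of embedding dimension L."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size < 2:
            raise ValueError("latent state must be a vector of length >= 2")
        if not np.isfinite(self.y).all():
            raise ValueError("latent state has non-finite entries")

    @property
    def L(self) -> int:
        return self.y.size


@dataclass
class CompanionForward:
    """Forward companion operator; ``a`` is its trainable last row."""

    a: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 1 or self.a.size < 2:
            raise ValueError("coefficient vector must have length >= 2")

    @property
    def L(self) -> int:
        return self.a.size


@dataclass
class CompanionBackward:
    """Backward companion operator; ``b`` is its trainable first row."""

    b: np.ndarray

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        if self.b.ndim != 1 or self.b.size < 2:
            raise ValueError("coefficient vector must have length >= 2")

    @property
    def L(self) -> int:
        return self.b.size


def _as_vec(state: LatentState | np.ndarray) -> np.ndarray:
    return state.y if isinstance(state, LatentState) else np.asarray(state, dtype=float)


def apply_forward(op: CompanionForward, state: LatentState | np.ndarray) -> LatentState:
    """One forward step: shift up and predict the new last entry as a . y."""
    y = _as_vec(state)
    if y.size != op.L:
        raise ValueError(f"operator has L={op.L}, state has length {y.size}")
    out = np.empty_like(y)
    out[:-1] = y[1:]
    out[-1] = op.a @ y
    return LatentState(out)


def apply_backward(op: CompanionBackward, state: LatentState | np.ndarray) -> LatentState:
    """One backward step: shift down and predict the new first entry as b . y."""
    y = _as_vec(state)
    if y.size != op.L:
        raise ValueError(f"operator has L={op.L}, state has length {y.size}")
    out = np.empty_like(y)
    out[1:] = y[:-1]
    out[0] = op.b @ y
    return LatentState(out)


def k_step(
    op: CompanionForward | CompanionBackward,
    state: LatentState | np.ndarray,
    k: int,
) -> LatentState:
    """Apply the operator ``k`` times (k = 0 is the identity)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    apply = apply_forward if isinstance(op, CompanionForward) else apply_backward
    cur = LatentState(_as_vec(state).copy())
    for _ in range(k):
        cur = apply(op, cur)
    return cur


def materialize(op: CompanionForward | CompanionBackward) -> np.ndarray:
    """Dense L x L matrix of the companion operator."""
    L = op.L
    m = np.zeros((L, L))
    if isinstance(op, CompanionForward):
        m[:-1, 1:] = np.eye(L - 1)
        m[-1, :] = op.a
    else:
        m[1:, :-1] = np.eye(L - 1)
        m[0, :] = op.b
    return m


def inverse_companion(op: CompanionForward) -> CompanionBackward:
    """Backward operator realizing the exact inverse dynamics of ``op``.

    Solving the last-row recurrence y_{t+L-1} = a1 y_{t-1} + sum_{i>=2}
    a_i y_{t+i-2} for y_{t-1} gives b = (-a2/a1, ..., -aL/a1, 1/a1);
    requires a1 != 0.
    """
    a = op.a
    if a[0] == 0:
        raise ValueError("inverse dynamics require a1 != 0")
    b = np.empty_like(a)
    b[:-1] = -a[1:] / a[0]
    b[-1] = 1.0 / a[0]
    return CompanionBackward(b)


def fit_companion_lsq(series: list[LatentState] | np.ndarray) -> CompanionForward:
    """Least-squares estimate of the forward coefficients a.

    ``series`` is a sequence of consecutive delay states (each length L, at
    least L+1 of them).  Each consecutive pair contributes one equation
    a . Y_t = last entry of Y_{t+1}.  Exact when the data really follow a
    companion recurrence and are noiseless.
    """
    if isinstance(series, np.ndarray):
        states = np.asarray(series, dtype=float)
    else:
        states = np.stack([_as_vec(s) for s in series])
    if states.ndim != 2:
        raise ValueError("series must be a sequence of equal-length states")
    m, L = states.shape
    if m < L + 1:
        raise ValueError(f"need at least L+1={L + 1} consecutive states, got {m}")
    X = states[:-1]
    z = states[1:, -1]
    if np.linalg.matrix_rank(X) < L:
        raise SingularFitError(
            "delay-state design matrix is rank deficient; the series does not "
            "excite all L delay coordinates"
        )
    a, *_ = np.linalg.lstsq(X, z, rcond=None)
    return CompanionForward(a)


# ---------------------------------------------------------------------------
# serialization


def operators_to_json(
    fwd: CompanionForward, bwd: CompanionBackward, path: str | Path | None = None
) -> str:
    if fwd.L != bwd.L:
        raise ValueError("forward and backward operators disagree on L")
    text = json.dumps({"L": fwd.L, "a": fwd.a.tolist(), "b": bwd.b.tolist()})
    if path is not None:
        Path(path).write_text(text)
    return text


def operators_from_json(source: str | Path) -> tuple[CompanionForward, CompanionBackward]:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    blob = json.loads(text)
    fwd = CompanionForward(np.asarray(blob["a"], dtype=float))
    bwd = CompanionBackward(np.asarray(blob["b"], dtype=float))
    if fwd.L != blob["L"] or bwd.L != blob["L"]:
        raise ValueError("coefficient lengths disagree with declared L")
    return fwd, bwd
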