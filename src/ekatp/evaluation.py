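"""Forecast quality metrics and robustness sweeps.

Predictive error is the per-step mean squared error across state
dimensions; PCC and RMSE compare whole predicted and true trajectory
blocks.  ``summarize_runs`` and ``paired_significance`` aggregate the
error at a fixed horizon over repeated, independently seeded datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorCurve",
    "EvaluationReport",
    "predictive_error",
    "pcc",
    "rmse",
    "summarize_runs",
    "paired_significance",
    "noise_sweep",
]


@dataclass
class ErrorCurve:
    """Per-step predictive error along a forecast horizon."""

    error: np.ndarray
    model: str = ""
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.error = np.asarray(self.error, dtype=float)
        if (self.error < 0).any():
            raise ValueError("predictive error cannot be negative")

    @property
    def steps(self) -> np.ndarray:
        return np.arange(1, self.error.size + 1)


@dataclass
class EvaluationReport:
    pcc: float
    rmse: float
    curve: ErrorCurve | None = None
    summary: dict = field(default_factory=dict)
    p_value: float | None = None

    def __post_init__(self):
        if not -1.0 <= self.pcc <= 1.0 + 1e-12:
            raise ValueError("PCC out of [-1, 1]")
        if self.rmse < 0:
            raise ValueError("RMSE cannot be negative")


def _blocks(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(getattr(pred, "values", pred), dtype=float)
    t = np.asarray(getattr(truth, "values", truth), dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p, t


def predictive_error(pred, truth, model: str = "", condition: dict | None = None) -> ErrorCurve:
    """Per-step MSE across the n state dimensions of (n, p) blocks."""
    p, t = _blocks(pred, truth)
    err = np.mean((p - t) ** 2, axis=0)
    return ErrorCurve(err, model=model, condition=condition or {})


def pcc(pred, truth) -> float:
    """Pearson correlation between predicted and true blocks, flattened
    across state dimensions."""
    p, t = _blocks(pred, truth)
    p, t = p.ravel(), t.ravel()
    dp, dt_ = p - p.mean(), t - t.mean()
    denom = np.sqrt((dp ** 2).sum() * (dt_ ** 2).sum())
    if denom == 0:
        raise ValueError("PCC undefined for zero-variance input")
    return float((dp * dt_).sum() / denom)


def rmse(pred, truth) -> float:
    """Root of the mean over steps of the squared Euclidean per-step residual."""
    p, t = _blocks(pred, truth)
    if p.ndim == 1:
        p, t = p[None, :], t[None, :]
    return float(np.sqrt(np.mean(np.sum((p - t) ** 2, axis=0))))


def summarize_runs(errors_at_step) -> dict[str, float]:
    """Min / max / mean / sample variance of a per-run error collection."""
    e = np.asarray(list(errors_at_step), dtype=float)
    if e.size < 2:
        raise ValueError("need at least two runs to summarize")
    return {
        "min": float(e.min()),
        "max": float(e.max()),
        "avg": float(e.mean()),
        "var": float(e.var(ddof=1)),
    }


def paired_significance(errors_a, errors_b, method: str = "wilcoxon") -> float:
    """Two-sided paired-test p-value comparing per-dataset errors.

    ``method`` is ``"wilcoxon"`` (signed-rank, default) or ``"ttest"``
    (paired t).  Identical samples return p = 1.
    """
    a = np.asarray(list(errors_a), dtype=float)
    b = np.asarray(list(errors_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least five pairs")
    if np.allclose(a, b):
        return 1.0
    if method == "wilcoxon":
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    if method == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    raise ValueError(f"unknown method {method!r}")


def noise_sweep(model_cfg: dict, system_cfg: dict, sigmas, seed: int = 0) -> pd.DataFrame:
    """Full simulate-train-predict-score run per noise intensity.

    Returns a DataFrame with columns ``sigma``, ``pcc``, ``rmse``; each row
    is one independent, seeded end-to-end run at that noise level.  The
    heavy lifting is the experiment pipeline; see
    :func:`ekatp.experiments.run_single`.
    """
    from .experiments import run_single  # local import to avoid a cycle

    rows = []
    for sigma in sigmas:
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        res = run_single({**system_cfg, "sigma": float(sigma)}, model_cfg, seed=seed)
        rows.append({"sigma": float(sigma), "pcc": res["pcc"], "rmse": res["rmse"]})
    return pd.DataFrame(rows)
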