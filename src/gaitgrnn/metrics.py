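"""Error-analysis metrics for predicted vs measured joint-angle series."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["Metrics", "compute_metrics", "cycle_extreme_errors"]


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson correlation is required for a constant series."""


class Metrics(NamedTuple):
    rmse: float
    mre: float
    gamma: float
    mre_excluded: int


def compute_metrics(
    pred: np.ndarray,
    actual: np.ndarray,
    mre_floor_frac: float = 1e-6,
    require_gamma: bool = False,
) -> Metrics:
    """RMSE, mean relative error and Pearson correlation.

    RMSE = sqrt(mean((pred - actual)^2));
    MRE  = mean(|(pred - actual) / pred|) — the relative error is taken
    against the prediction. Because joint angles cross zero, samples whose
    |pred| falls below ``mre_floor_frac`` times the prediction range are
    excluded from the MRE average; the number excluded is reported so the
    guard is never silent. gamma is the standard Pearson correlation
    coefficient (symmetric in its arguments); it is NaN when either series
    is constant, since RMSE and MRE remain perfectly well-defined there.
    Pass ``require_gamma=True`` to raise instead.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    if pred.size < 2:
        raise ValueError("need at least 2 samples")

    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))

    floor = mre_floor_frac * float(np.ptp(pred))
    keep = np.abs(pred) > floor
    n_excluded = int(np.sum(~keep))
    if np.any(keep):
        mre = float(np.mean(np.abs((pred[keep] - actual[keep]) / pred[keep])))
    else:
        mre = float("nan")

    if np.ptp(pred) == 0.0 or np.ptp(actual) == 0.0:
        if require_gamma:
            raise UndefinedCorrelationError("correlation undefined for a constant series")
        gamma = float("nan")
    else:
        gamma = float(np.corrcoef(pred, actual)[0, 1])
    return Metrics(rmse=rmse, mre=mre, gamma=gamma, mre_excluded=n_excluded)


def cycle_extreme_errors(
    pred: np.ndarray, actual: np.ndarray, cycle_id: np.ndarray
) -> tuple[float, float]:
    """Mean maximum positive and mean maximum negative signed error.

    The signed error (pred - actual) is grouped by gait cycle; within each
    cycle the maximum and minimum are taken, and the means over cycles are
    returned as (mean_max_pos, mean_max_neg). Cycles at the span
    boundaries may be partial; they are kept, since a truncated cycle's
    extremes are still the extremes the wearer experienced.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    cycle_id = np.asarray(cycle_id)
    if not (pred.shape == actual.shape == cycle_id.shape):
        raise ValueError("pred, actual and cycle_id must have identical shapes")
    if pred.size == 0:
        raise ValueError("no samples: need at least one gait cycle")
    err = pred - actual
    ids = np.unique(cycle_id)
    maxima = [float(np.max(err[cycle_id == c])) for c in ids]
    minima = [float(np.min(err[cycle_id == c])) for c in ids]
    return float(np.mean(maxima)), float(np.mean(minima))
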