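"""General regression neural network (GRNN) and golden-section bandwidth
optimization.

A GRNN is a lazy kernel regressor (Nadaraya-Watson with a Gaussian
kernel): the prediction at a query x is the kernel-weighted average of the
stored training targets,

    y_hat(x) = sum_i Y_i exp(-D_i^2 / (2 sigma^2)) /
               sum_i     exp(-D_i^2 / (2 sigma^2)),

with D_i^2 the squared Euclidean distance between x and stored pattern X_i.
The smoothing factor sigma is the network's only free parameter; it is
chosen by a golden-section line search on the leave-one-out mean squared
error. Exponentials are stabilized by subtracting the per-query minimum
distance, which cancels in the ratio and keeps predictions finite for
sigma values far below the pattern spacing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRNN",
    "GoldenSectionConfig",
    "fit",
    "loo_mse",
    "golden_section_search",
    "optimize_sigma",
]

_INV_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0  # 0.618...


@dataclass(frozen=True)
class GoldenSectionConfig:
    """Search interval and termination width for the sigma line search.

    The lower bound stands in for the open end of the (0, 0.2) search
    range; the search stops when the bracketing interval is narrower than
    ``epsilon`` and returns the interval midpoint.
    """

    a: float = 1e-6
    b: float = 0.2
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.a < self.b:
            raise ValueError(f"need 0 < a < b, got a={self.a}, b={self.b}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


def _validate_training(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"pattern/target row mismatch: {X.shape[0]} vs {Y.shape[0]}")
    if X.shape[0] < 1:
        raise ValueError("need at least one training pattern")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("training data contain non-finite values")
    return X, Y


def _sq_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0."""
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        - 2.0 * (A @ B.T)
        + np.sum(B**2, axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


class GRNN:
    """A fitted GRNN: stored patterns, stored targets and a bandwidth.

    Fitting is pattern storage — there is no iterative training. Use
    :func:`optimize_sigma` to pick the bandwidth by leave-one-out search.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray, sigma: float, norm_params=None):
        if not sigma > 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        self.X, self.Y = _validate_training(X, Y)
        self.sigma = float(sigma)
        self.norm_params = norm_params
        self.trace_: list[tuple[float, float]] | None = None

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        """Kernel-weighted average of stored targets at each query row.

        The per-query minimum D^2 is subtracted inside the exponentials
        (it cancels between numerator and denominator), so the weights are
        well-defined even when every raw exponential would underflow.
        Every output component is a convex combination of stored targets.
        """
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if Xq.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"query dimension {Xq.shape[1]} != pattern dimension {self.X.shape[1]}"
            )
        d2 = _sq_distances(Xq, self.X)
        d2 -= d2.min(axis=1, keepdims=True)
        w = np.exp(-d2 / (2.0 * self.sigma**2))
        return (w @ self.Y) / np.sum(w, axis=1, keepdims=True)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        doc = {
            "sigma": self.sigma,
            "patterns": self.X.tolist(),
            "targets": self.Y.tolist(),
        }
        if self.norm_params is not None:
            doc["norm_params"] = json.loads(self.norm_params.to_json())
        return doc

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, doc: dict) -> "GRNN":
        from .preprocessing import NormalizationParams

        norm = doc.get("norm_params")
        return cls(
            np.asarray(doc["patterns"], dtype=float),
            np.asarray(doc["targets"], dtype=float),
            float(doc["sigma"]),
            norm_params=NormalizationParams.from_json(json.dumps(norm)) if norm else None,
        )

    @classmethod
    def from_json(cls, text: str) -> "GRNN":
        return cls.from_dict(json.loads(text))


def fit(X: np.ndarray, Y: np.ndarray, sigma: float, norm_params=None) -> GRNN:
    """Store the training patterns and targets with a fixed bandwidth."""
    return GRNN(X, Y, sigma, norm_params=norm_params)


def _loo_objective(X: np.ndarray, Y: np.ndarray):
    """Closure computing leave-one-out MSE as a function of sigma.

    The pairwise distance matrix does not depend on sigma, so it is built
    once and reused across every evaluation of the line search.
    """
    X, Y = _validate_training(X, Y)
    if X.shape[0] < 2:
        raise ValueError("leave-one-out objective needs at least 2 samples")
    d2 = _sq_distances(X, X)
    np.fill_diagonal(d2, np.inf)  # exclude each pattern from its own prediction
    offset = d2.min(axis=1, keepdims=True)

    def objective(sigma: float) -> float:
        if not sigma > 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        w = np.exp(-(d2 - offset) / (2.0 * sigma**2))
        pred = (w @ Y) / np.sum(w, axis=1, keepdims=True)
        return float(np.mean((Y - pred) ** 2))

    return objective


def loo_mse(X: np.ndarray, Y: np.ndarray, sigma: float) -> float:
    """Leave-one-out mean squared error of a GRNN with bandwidth ``sigma``.

    Each sample is predicted from all other samples; errors are averaged
    over samples and output dimensions. In-sample MSE is degenerate for a
    GRNN (it tends to 0 as sigma -> 0 for distinct patterns), so the
    bandwidth objective is evaluated leave-one-out.
    """
    return _loo_objective(X, Y)(sigma)


class OptimizationError(RuntimeError):
    """Raised when the line-search objective returns a non-finite value."""


def golden_section_search(
    objective, config: GoldenSectionConfig = GoldenSectionConfig()
) -> tuple[float, list[tuple[float, float]]]:
    """Minimize a scalar function on [a, b] by golden-section contraction.

    Each iteration shrinks the bracketing interval by the golden ratio and
    reuses one interior evaluation, so only one new objective call is made
    per iteration after the first two. Ties between the interior values are
    broken toward the left subinterval for determinism. Returns the final
    interval midpoint and the full (sigma, value) evaluation trace.
    """
    a, b = config.a, config.b
    trace: list[tuple[float, float]] = []

    def f(x: float) -> float:
        v = float(objective(x))
        if not math.isfinite(v):
            raise OptimizationError(f"objective returned non-finite value {v} at sigma={x}")
        trace.append((x, v))
        return v

    c = b - _INV_GOLDEN * (b - a)
    d = a + _INV_GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) >= config.epsilon:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _INV_GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INV_GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2.0, trace


def optimize_sigma(
    X: np.ndarray,
    Y: np.ndarray,
    config: GoldenSectionConfig = GoldenSectionConfig(),
    norm_params=None,
) -> GRNN:
    """Fit a GRNN with the bandwidth minimizing the leave-one-out MSE.

    The golden-section trace is attached to the returned model as
    ``model.trace_``.
    """
    objective = _loo_objective(X, Y)
    sigma_opt, trace = golden_section_search(objective, config)
    model = GRNN(X, Y, sigma_opt, norm_params=norm_params)
    model.trace_ = trace
    return model
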