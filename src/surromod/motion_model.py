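"""Amplitude + derivative tumor position model.

Models the intra-fractional tumor position as an affine function of a
baseline-corrected surrogate amplitude ``A`` and its time derivative ``A'``::

    x(A, A') = x0 + A * xA + A' * xAprime

Training is ordinary least squares on concurrent (surrogate, position)
pairs; evaluation reports the mean and 90th percentile of the Euclidean
residual magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._piecewise import window_mean
from .surrogates import SurrogateTrace

__all__ = [
    "MotionModelParams",
    "TrainingPair",
    "TrainingSet",
    "ResidualSummary",
    "DegenerateDesignError",
    "estimate_derivative",
    "sample_surrogate_at",
    "center_positions",
    "fit_low_model",
    "fit_amplitude_only",
    "predict_position",
    "compute_residuals",
    "summarize_residuals",
]

#: residual percentile reported alongside the mean
P90 = 90.0


class DegenerateDesignError(ValueError):
    """Raised when the [1, A, A'] design matrix is rank deficient."""


@dataclass
class MotionModelParams:
    """Fitted model vectors (mm, mm per surrogate unit, mm*s per surrogate unit)."""

    x0: np.ndarray
    xA: np.ndarray
    xAprime: np.ndarray
    surrogate: str | None = None

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float).reshape(3)
        self.xA = np.asarray(self.xA, dtype=float).reshape(3)
        self.xAprime = np.asarray(self.xAprime, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.x0)) and np.all(np.isfinite(self.xA))
                and np.all(np.isfinite(self.xAprime))):
            raise ValueError("model parameters must be finite")


@dataclass
class TrainingPair:
    A: float
    Aprime: float
    x: np.ndarray
    time: float = 0.0


@dataclass
class TrainingSet:
    """Array-of-structs view of concurrent surrogate/position samples."""

    A: np.ndarray
    Aprime: np.ndarray
    x: np.ndarray          # (n, 3) mm
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).ravel()
        self.Aprime = np.asarray(self.Aprime, dtype=float).ravel()
        self.x = np.asarray(self.x, dtype=float).reshape(-1, 3)
        if not (self.A.size == self.Aprime.size == self.x.shape[0]):
            raise ValueError("inconsistent training set lengths")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float).ravel()

    def __len__(self) -> int:
        return self.A.size

    def subset(self, idx) -> "TrainingSet":
        t = None if self.times is None else self.times[idx]
        return TrainingSet(self.A[idx], self.Aprime[idx], self.x[idx], t)

    @classmethod
    def from_pairs(cls, pairs: Iterable[TrainingPair]) -> "TrainingSet":
        pairs = list(pairs)
        return cls(
            A=np.array([p.A for p in pairs]),
            Aprime=np.array([p.Aprime for p in pairs]),
            x=np.array([np.asarray(p.x, dtype=float) for p in pairs]),
            times=np.array([p.time for p in pairs]),
        )


@dataclass
class ResidualSummary:
    residual_vectors: np.ndarray  # (n, 3) mm
    magnitudes: np.ndarray        # (n,) mm
    mean: float                   # mm
    p90: float                    # mm
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = int(self.magnitudes.size)


def _as_training_set(training) -> TrainingSet:
    if isinstance(training, TrainingSet):
        return training
    return TrainingSet.from_pairs(training)


def estimate_derivative(trace: SurrogateTrace) -> SurrogateTrace:
    """Central-difference time derivative of a trace (one-sided at the ends).

    Interior samples use ``(v[k+1] - v[k-1]) / (t[k+1] - t[k-1])``; this is
    exact for affine traces and the convention shared with the synthetic
    trajectory generator.
    """
    t = trace.times
    v = trace.values
    if t.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (t[2:] - t[:-2])
    d[0] = (v[1] - v[0]) / (t[1] - t[0])
    d[-1] = (v[-1] - v[-2]) / (t[-1] - t[-2])
    return SurrogateTrace(times=t.copy(), values=d, label=trace.label,
                          baseline_corrected=trace.baseline_corrected,
                          units=f"{trace.units}/s")


def sample_surrogate_at(trace: SurrogateTrace, derivative_trace: SurrogateTrace,
                        acquisition_times, exposure: float,
                        max_gap: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Exposure-window means ``(A, A')`` of the traces at each acquisition.

    Both traces are treated as piecewise linear; the mean over
    ``[t - exposure/2, t + exposure/2]`` is computed in closed form.
    Acquisitions outside the trace span or straddling a sampling gap
    longer than `max_gap` seconds raise ``ValueError``.
    """
    tq = np.asarray(acquisition_times, dtype=float)
    A = window_mean(trace.times, trace.values, tq, exposure, max_gap=max_gap)
    Ap = window_mean(derivative_trace.times, derivative_trace.values, tq,
                     exposure, max_gap=max_gap)
    return A, Ap


def center_positions(positions) -> np.ndarray:
    """Subtract the component-wise median (per-session setup removal)."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if pos.shape[0] == 0:
        raise ValueError("no positions to center")
    return pos - np.median(pos, axis=0)


def _design(A: np.ndarray, Aprime: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(A), A, Aprime])


def _check_rank(design: np.ndarray, columns: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the most plausible deficient column for the error message
        for j, name in enumerate(columns):
            if j > 0 and np.ptp(design[:, j]) < 1e-12 * max(1.0, np.max(np.abs(design[:, j]))):
                raise DegenerateDesignError(
                    f"design rank {rank} < {design.shape[1]}: column '{name}' is constant")
        raise DegenerateDesignError(
            f"design rank {rank} < {design.shape[1]}: columns {columns} are collinear")


def fit_low_model(training, surrogate: str | None = None) -> MotionModelParams:
    """Least-squares fit of ``x0, xA, xAprime`` to >= 4 training pairs."""
    ts = _as_training_set(training)
    if len(ts) < 4:
        raise ValueError(f"need at least 4 training pairs, got {len(ts)}")
    X = _design(ts.A, ts.Aprime)
    _check_rank(X, ("intercept", "A", "Aprime"))
    coef, *_ = np.linalg.lstsq(X, ts.x, rcond=None)
    return MotionModelParams(x0=coef[0], xA=coef[1], xAprime=coef[2],
                             surrogate=surrogate)


def fit_amplitude_only(training, surrogate: str | None = None) -> MotionModelParams:
    """Reduced model with the derivative term forced to zero."""
    ts = _as_training_set(training)
    if len(ts) < 4:
        raise ValueError(f"need at least 4 training pairs, got {len(ts)}")
    X = np.column_stack([np.ones_like(ts.A), ts.A])
    if np.linalg.matrix_rank(X) < 2:
        raise DegenerateDesignError("amplitude column is constant")
    coef, *_ = np.linalg.lstsq(X, ts.x, rcond=None)
    return MotionModelParams(x0=coef[0], xA=coef[1], xAprime=np.zeros(3),
                             surrogate=surrogate)


def predict_position(params: MotionModelParams, A, Aprime) -> np.ndarray:
    """Model position(s); scalar inputs give a 3-vector, arrays an (n, 3)."""
    A = np.asarray(A, dtype=float)
    Ap = np.asarray(Aprime, dtype=float)
    out = (params.x0 + np.multiply.outer(A, params.xA)
           + np.multiply.outer(Ap, params.xAprime))
    return out


def summarize_residuals(residual_vectors) -> ResidualSummary:
    vec = np.asarray(residual_vectors, dtype=float).reshape(-1, 3)
    if vec.shape[0] == 0:
        raise ValueError("no residuals to summarize")
    mags = np.linalg.norm(vec, axis=1)
    return ResidualSummary(
        residual_vectors=vec,
        magnitudes=mags,
        mean=float(np.mean(mags)),
        p90=float(np.percentile(mags, P90)),  # linear interpolation convention
    )


def compute_residuals(params: MotionModelParams, validation) -> ResidualSummary:
    """Residuals (modeled minus measured) over a validation set."""
    vs = _as_training_set(validation)
    if len(vs) == 0:
        raise ValueError("empty validation set")
    pred = predict_position(params, vs.A, vs.Aprime)
    return summarize_residuals(pred - vs.x)
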