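"""Exact evaluation and integration of piecewise-linear time series.

Several pipeline stages treat a sampled trace as the piecewise-linear
interpolant of its samples (surrogate traces, derivative traces, simulated
tumor trajectories).  The helpers here evaluate that interpolant and its
antiderivative *exactly*, so that window averages computed in different
modules agree to machine precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["antiderivative_at", "window_mean", "check_window_gaps"]


def _validate(times: np.ndarray, values: np.ndarray) -> None:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need at least two samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.asarray(values).shape[0] != times.shape[0]:
        raise ValueError("times and values length mismatch")


def antiderivative_at(times: np.ndarray, values: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Evaluate ``F(t) = integral of the piecewise-linear interpolant`` at `query`.

    ``F(times[0]) = 0``.  Queries must lie inside ``[times[0], times[-1]]``.
    Exact (up to rounding) because between knots the interpolant is linear,
    hence its antiderivative is the quadratic evaluated here in closed form.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _validate(times, values)
    query = np.asarray(query, dtype=float)
    if np.any(query < times[0]) or np.any(query > times[-1]):
        raise ValueError("query time outside the sampled span")
    dt = np.diff(times)
    # cumulative trapezoid up to each knot
    F = np.concatenate([[0.0], np.cumsum(0.5 * (values[1:] + values[:-1]) * dt)])
    idx = np.clip(np.searchsorted(times, query, side="right") - 1, 0, times.size - 2)
    h = query - times[idx]
    slope = (values[idx + 1] - values[idx]) / dt[idx]
    return F[idx] + values[idx] * h + 0.5 * slope * h * h


def check_window_gaps(times: np.ndarray, starts: np.ndarray, stops: np.ndarray,
                      max_gap: float) -> None:
    """Raise if any sampling gap strictly inside a window exceeds `max_gap`."""
    times = np.asarray(times, dtype=float)
    gaps = np.diff(times)
    for t0, t1 in zip(np.atleast_1d(starts), np.atleast_1d(stops)):
        i0 = np.searchsorted(times, t0, side="right") - 1
        i1 = np.searchsorted(times, t1, side="left")
        i0 = max(i0, 0)
        seg = gaps[i0:max(i1, i0 + 1)]
        if seg.size and np.max(seg) > max_gap:
            raise ValueError(
                f"sampling gap of {np.max(seg):.3f} s inside window "
                f"[{t0:.3f}, {t1:.3f}] exceeds {max_gap:.3f} s")


def window_mean(times: np.ndarray, values: np.ndarray, centers: np.ndarray,
                exposure: float, max_gap: float | None = None) -> np.ndarray:
    """Mean of the piecewise-linear interpolant over ``[c - e/2, c + e/2]``.

    Parameters
    ----------
    centers : window midpoints (s); every window must lie inside the span.
    exposure : window width (s), > 0.
    max_gap : optionally reject windows that straddle sampling gaps longer
        than this (seconds).
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    centers = np.asarray(centers, dtype=float)
    t0 = centers - exposure / 2.0
    t1 = centers + exposure / 2.0
    if max_gap is not None:
        check_window_gaps(times, t0, t1, max_gap)
    return (antiderivative_at(times, values, t1)
            - antiderivative_at(times, values, t0)) / exposure
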