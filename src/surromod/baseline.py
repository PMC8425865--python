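"""Running-median exhalation baseline detection and subtraction.

Breathing cycles are segmented by their full-exhalation minima; the
baseline is the linear interpolation of a symmetric running median over
seven consecutive minima values (window shrunk symmetrically near the
record edges), and is subtracted from the trace so that exhalation
minima sit near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .surrogates import SurrogateTrace

__all__ = [
    "CycleSegmentation",
    "BaselineFunction",
    "detect_exhalation_extrema",
    "compute_baseline",
    "baseline_correct",
]

#: running-median window, in exhalation minima (symmetric: 3 each side)
MEDIAN_WINDOW = 7


@dataclass
class CycleSegmentation:
    minima_times: np.ndarray
    minima_values: np.ndarray
    prominence_threshold: float = 0.3
    min_cycle_duration: float = 1.5

    def __post_init__(self) -> None:
        self.minima_times = np.asarray(self.minima_times, dtype=float).ravel()
        self.minima_values = np.asarray(self.minima_values, dtype=float).ravel()
        if self.minima_times.size != self.minima_values.size:
            raise ValueError("times/values length mismatch")
        if self.minima_times.size > 1 and np.any(np.diff(self.minima_times) <= 0):
            raise ValueError("minima times must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(self.minima_times.size - 1, 0)


@dataclass
class BaselineFunction:
    """Piecewise-linear baseline with constant extrapolation beyond the knots."""

    knot_times: np.ndarray
    knot_values: np.ndarray

    def __post_init__(self) -> None:
        self.knot_times = np.asarray(self.knot_times, dtype=float).ravel()
        self.knot_values = np.asarray(self.knot_values, dtype=float).ravel()
        if self.knot_times.size == 0:
            raise ValueError("baseline needs at least one knot")
        if np.any(np.diff(self.knot_times) <= 0):
            raise ValueError("knot times must be strictly increasing")

    def __call__(self, t) -> np.ndarray:
        # np.interp clamps to the edge values, i.e. constant extrapolation
        return np.interp(np.asarray(t, dtype=float), self.knot_times, self.knot_values)


def detect_exhalation_extrema(trace: SurrogateTrace,
                              prominence_threshold: float = 0.3,
                              min_cycle_duration: float = 1.5) -> CycleSegmentation:
    """Locate full-exhalation minima of a breathing trace.

    A first pass with only the minimum-separation constraint estimates the
    median peak-to-peak amplitude; the final minima must then have a
    prominence of at least ``prominence_threshold`` times that amplitude.
    Flat plateaus (rest at full exhalation) are detected at their midpoint.
    """
    v = trace.values
    t = trace.times
    if v.size < 4:
        raise ValueError("trace too short for cycle detection")
    dt = float(np.median(np.diff(t)))
    distance = max(int(round(min_cycle_duration / dt)), 1)
    kw = dict(distance=distance, plateau_size=(1, None))
    cand_min, _ = find_peaks(-v, **kw)
    cand_max, _ = find_peaks(v, **kw)
    if cand_min.size == 0 or cand_max.size == 0:
        raise ValueError("no cycles detected")
    p2p = float(np.median(v[cand_max]) - np.median(v[cand_min]))
    if p2p <= 0:
        raise ValueError("no cycles detected (non-positive peak-to-peak amplitude)")
    minima, _ = find_peaks(-v, prominence=prominence_threshold * p2p, **kw)
    if minima.size == 0:
        raise ValueError("no cycles detected")
    return CycleSegmentation(minima_times=t[minima], minima_values=v[minima],
                             prominence_threshold=prominence_threshold,
                             min_cycle_duration=min_cycle_duration)


def compute_baseline(trace: SurrogateTrace, seg: CycleSegmentation) -> BaselineFunction:
    """Symmetric running median (7 minima wide) over the exhalation minima.

    At each minimum k the knot value is the median of minima values in the
    window {k-3, ..., k+3}; near the edges the window shrinks symmetrically
    (k-w ... k+w with w = min(3, k, n-1-k)).  With fewer than 7 minima in
    total, every knot uses all of them.  An even count medians as the mean
    of the two central values.
    """
    m = seg.minima_values
    if m.size == 0:
        raise ValueError("empty segmentation")
    half = MEDIAN_WINDOW // 2
    knots = np.empty_like(m)
    n = m.size
    if n < MEDIAN_WINDOW:
        knots[:] = np.median(m)
    else:
        for k in range(n):
            w = min(half, k, n - 1 - k)
            knots[k] = np.median(m[k - w:k + w + 1])
    return BaselineFunction(knot_times=seg.minima_times.copy(), knot_values=knots)


def baseline_correct(trace: SurrogateTrace, baseline: BaselineFunction) -> SurrogateTrace:
    """Subtract the baseline; exhalation minima of the output sit near zero."""
    corrected = trace.values - baseline(trace.times)
    return SurrogateTrace(times=trace.times.copy(), values=corrected,
                          label=trace.label, baseline_corrected=True,
                          units=trace.units)
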