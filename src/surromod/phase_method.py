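"""Phase-binned comparator (4DCT-style) for tumor position lookup.

The breathing phase is the linear fraction of elapsed time between
consecutive exhalation minima (0 at full exhalation).  Training positions
are grouped into equal-width phase bins; a validation position is compared
against the mean training position of its bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import CycleSegmentation
from .motion_model import ResidualSummary, summarize_residuals
from .surrogates import SurrogateTrace

__all__ = [
    "PhaseBinTable",
    "compute_phase",
    "build_phase_bins",
    "evaluate_phase_method",
]


@dataclass
class PhaseBinTable:
    n_bins: int
    bin_positions: np.ndarray  # (n_bins, 3) mm
    bin_counts: np.ndarray     # (n_bins,)

    def __post_init__(self) -> None:
        self.bin_positions = np.asarray(self.bin_positions, dtype=float).reshape(-1, 3)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int).ravel()
        if self.bin_positions.shape[0] != self.n_bins or self.bin_counts.size != self.n_bins:
            raise ValueError("table size mismatch")

    def lookup(self, phases) -> np.ndarray:
        idx = _bin_index(np.asarray(phases, dtype=float), self.n_bins)
        return self.bin_positions[idx]


def compute_phase(trace: SurrogateTrace, seg: CycleSegmentation, times) -> np.ndarray:
    """Time-based breathing phase in [0, 1) at each queried time.

    Phase is the linear fraction of elapsed time between the enclosing
    exhalation minima; a query exactly at a minimum has phase 0.  Queries
    outside [first minimum, last minimum] raise ``ValueError``.
    """
    m = seg.minima_times
    if m.size < 2:
        raise ValueError("need at least two minima to define phases")
    tq = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(tq < m[0]) or np.any(tq > m[-1]):
        raise ValueError("queried time outside the first/last exhalation minimum")
    idx = np.clip(np.searchsorted(m, tq, side="right") - 1, 0, m.size - 2)
    phase = (tq - m[idx]) / (m[idx + 1] - m[idx])
    phase[np.isclose(phase, 1.0)] = 0.0  # a query at the closing minimum
    return phase


def _bin_index(phases: np.ndarray, n_bins: int) -> np.ndarray:
    return np.clip((phases * n_bins).astype(int), 0, n_bins - 1)


def build_phase_bins(phases, positions, n_bins: int = 10) -> PhaseBinTable:
    """Equal-width bins on [0, 1); bin position = mean of member positions.

    Empty bins inherit the position of the circularly nearest occupied bin.
    """
    phases = np.asarray(phases, dtype=float).ravel()
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if phases.size == 0:
        raise ValueError("no training samples")
    if phases.size != positions.shape[0]:
        raise ValueError("phases/positions length mismatch")
    idx = _bin_index(phases, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.zeros((n_bins, 3))
    np.add.at(sums, idx, positions)
    table = np.full((n_bins, 3), np.nan)
    occ = counts > 0
    table[occ] = sums[occ] / counts[occ, None]
    if not np.any(occ):
        raise ValueError("all bins empty")
    occupied = np.flatnonzero(occ)
    for b in np.flatnonzero(~occ):
        d = np.minimum((occupied - b) % n_bins, (b - occupied) % n_bins)
        table[b] = table[occupied[np.argmin(d)]]
    return PhaseBinTable(n_bins=n_bins, bin_positions=table, bin_counts=counts)


def evaluate_phase_method(table: PhaseBinTable, phases, positions) -> ResidualSummary:
    """Residuals of binned-position lookup against measured positions."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    modeled = table.lookup(phases)
    return summarize_residuals(modeled - positions)
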