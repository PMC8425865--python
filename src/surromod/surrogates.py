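"""Surface surrogate extraction from laser-line point-cloud frames.

Four scalar surrogates are extracted from each timestamped frame:

* ``AP`` — vertical surface height at a fixed abdominal (x, y) location,
* ``TP`` — vertical surface height at a fixed thoracic (x, y) location,
* ``RDM`` — mean Euclidean distance from the origin to every captured point,
* ``SDV`` — volume between the z = 0 plane and the surface over a fixed
  rectangular region of interest, integrated on a rectilinear grid.

Point heights at fixed coordinates are obtained by linear interpolation
along each laser line (polygonal chain) and then linearly across the
nearest lines in the craniocaudal direction, which compensates for the
small sliding of captured points during breathing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceFrame",
    "SurrogateConfig",
    "SurrogateTrace",
    "SurfaceInterpolationError",
    "interpolate_height",
    "extract_point_surrogate",
    "compute_rdm",
    "compute_sdv",
    "extract_rdm_trace",
    "extract_sdv_trace",
    "extract_all_surrogates",
]

SURROGATE_LABELS = ("AP", "RDM", "SDV", "TP")


class SurfaceInterpolationError(ValueError):
    """Raised when a query point cannot be interpolated from a frame."""


@dataclass
class SurfaceFrame:
    """One timestamped point cloud, points grouped by laser line id.

    ``lines`` maps a line id to an (n, 3) array of (x, y, z) mm.
    """

    time: float
    lines: Dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.lines = {int(k): np.asarray(v, dtype=float).reshape(-1, 3)
                      for k, v in self.lines.items()}
        if not any(len(v) for v in self.lines.values()):
            raise ValueError("frame has no points")
        for lid, pts in self.lines.items():
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"non-finite coordinates on line {lid}")
        self._line_y: Dict[int, float] | None = None

    def line_y(self) -> Dict[int, float]:
        """Representative craniocaudal coordinate per non-empty line."""
        if self._line_y is None:
            self._line_y = {lid: float(np.median(pts[:, 1]))
                            for lid, pts in self.lines.items() if len(pts)}
        return self._line_y

    def all_points(self) -> np.ndarray:
        return np.concatenate([pts for pts in self.lines.values() if len(pts)])

    @property
    def n_points(self) -> int:
        return sum(len(pts) for pts in self.lines.values())


@dataclass
class SurrogateConfig:
    """Fixed extraction coordinates (mm) and integration settings."""

    ap_location: tuple[float, float] = (0.0, -150.0)   # ~15 cm caudal of xiphoid
    tp_location: tuple[float, float] = (0.0, 0.0)      # xiphoid reference
    roi_center: tuple[float, float] = (0.0, -112.5)
    roi_size: tuple[float, float] = (150.0, 150.0)
    grid_spacing: float = 20.0
    n_nearest_lines: int = 3
    rdm_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    max_gap_s: float = 2.0

    def __post_init__(self) -> None:
        if min(self.roi_size) <= 0:
            raise ValueError("ROI sides must be positive")
        if not (0 < self.grid_spacing < min(self.roi_size)):
            raise ValueError("grid_spacing must be in (0, min ROI side)")
        if self.n_nearest_lines < 2:
            raise ValueError("need at least 2 nearest lines")


@dataclass
class SurrogateTrace:
    """A timestamped scalar surrogate signal."""

    times: np.ndarray
    values: np.ndarray
    label: str
    baseline_corrected: bool = False
    units: str = "mm"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.times.size != self.values.size:
            raise ValueError("times and values length mismatch")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _line_height_at(pts: np.ndarray, qx: float | np.ndarray) -> np.ndarray | None:
    """Height(s) at lateral coordinate(s) qx along one polygonal chain.

    Returns None when any query is outside the chain's lateral span.
    """
    order = np.argsort(pts[:, 0], kind="stable")
    xs = pts[order, 0]
    zs = pts[order, 2]
    q = np.atleast_1d(np.asarray(qx, dtype=float))
    if np.any(q < xs[0]) or np.any(q > xs[-1]):
        return None
    return np.interp(q, xs, zs)


def _nearest_lines(frame: SurfaceFrame, qy: float) -> list[int]:
    ys = frame.line_y()
    return sorted(ys, key=lambda lid: (abs(ys[lid] - qy), ys[lid]))


def _across_lines(qy: float, line_ys: np.ndarray, line_hs: np.ndarray) -> np.ndarray:
    order = np.argsort(line_ys)
    ys = line_ys[order]
    hs = line_hs[order]
    if qy < ys[0] or qy > ys[-1]:
        raise SurfaceInterpolationError(
            f"query y={qy:.1f} outside span [{ys[0]:.1f}, {ys[-1]:.1f}] of usable lines")
    return np.interp(qy, ys, hs)


def interpolate_height(frame: SurfaceFrame, query: tuple[float, float],
                       n_lines: int = 3) -> float:
    """Surface height (mm) at fixed (x, y), from the nearest laser lines.

    Within each of the `n_lines` nearest usable lines the height at the
    query x is found by linear interpolation along the chain; across lines
    the heights are linearly interpolated in y.  Lines that do not cover
    the query laterally are skipped in favor of the next nearest; fewer
    than two usable lines, or a query y outside their span, is an error.
    """
    qx, qy = float(query[0]), float(query[1])
    ys_map = frame.line_y()
    used_y, used_h = [], []
    for lid in _nearest_lines(frame, qy):
        h = _line_height_at(frame.lines[lid], qx)
        if h is None:
            continue
        used_y.append(ys_map[lid])
        used_h.append(h[0])
        if len(used_y) == n_lines:
            break
    if len(used_y) < 2:
        raise SurfaceInterpolationError(
            f"fewer than 2 lines cover x={qx:.1f} at t={frame.time:.3f}")
    return float(_across_lines(qy, np.array(used_y), np.array(used_h)))


def extract_point_surrogate(frames: Sequence[SurfaceFrame],
                            location: tuple[float, float],
                            config: SurrogateConfig | None = None,
                            label: str = "AP") -> SurrogateTrace:
    """Height-at-fixed-location trace; uninterpolable frames are skipped."""
    config = config or SurrogateConfig()
    if not frames:
        raise ValueError("no frames")
    times, values = [], []
    for frame in frames:
        try:
            z = interpolate_height(frame, location, config.n_nearest_lines)
        except SurfaceInterpolationError as exc:
            logger.warning("skipping frame t=%.3f for %s: %s", frame.time, label, exc)
            continue
        times.append(frame.time)
        values.append(z)
    if not times:
        raise SurfaceInterpolationError(f"no frame could be interpolated for {label}")
    return SurrogateTrace(np.array(times), np.array(values), label=label)


def compute_rdm(frame: SurfaceFrame,
                origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> float:
    """Mean Euclidean distance (mm) from `origin` to every captured point."""
    pts = frame.all_points()
    if pts.shape[0] == 0:
        raise ValueError("empty frame")
    return float(np.mean(np.linalg.norm(pts - np.asarray(origin, dtype=float), axis=1)))


def _grid_coords(lo: float, hi: float, step: float) -> np.ndarray:
    """Grid from lo to hi at `step`, final partial interval included."""
    n_full = int(np.floor((hi - lo) / step + 1e-9))
    coords = lo + step * np.arange(n_full + 1)
    if coords[-1] < hi - 1e-9:
        coords = np.append(coords, hi)
    else:
        coords[-1] = hi
    return coords


def _grid_heights(frame: SurfaceFrame, xs: np.ndarray, ys: np.ndarray,
                  n_lines: int) -> np.ndarray:
    """Heights on the tensor grid ys x xs, row-vectorized across lines."""
    ys_map = frame.line_y()
    H = np.empty((ys.size, xs.size))
    for j, qy in enumerate(ys):
        used_y, used_h = [], []
        for lid in _nearest_lines(frame, qy):
            h = _line_height_at(frame.lines[lid], xs)
            if h is None:
                continue
            used_y.append(ys_map[lid])
            used_h.append(h)
            if len(used_y) == n_lines:
                break
        if len(used_y) < 2:
            raise SurfaceInterpolationError(
                f"grid node row y={qy:.1f} not interpolable at t={frame.time:.3f}")
        order = np.argsort(used_y)
        yy = np.asarray(used_y)[order]
        hh = np.asarray(used_h)[order]
        if qy < yy[0] or qy > yy[-1]:
            raise SurfaceInterpolationError(
                f"grid node row y={qy:.1f} outside usable line span at t={frame.time:.3f}")
        # linear interpolation in y, vectorized over the x row
        k = int(np.clip(np.searchsorted(yy, qy, side="right") - 1, 0, yy.size - 2))
        w = (qy - yy[k]) / (yy[k + 1] - yy[k])
        H[j] = (1.0 - w) * hh[k] + w * hh[k + 1]
    return H


def compute_sdv(frame: SurfaceFrame, config: SurrogateConfig | None = None) -> float:
    """Volume (mm^3) between the z = 0 plane and the surface over the ROI.

    Heights are sampled on a rectilinear grid (spacing ``grid_spacing``,
    final partial interval included so ROI coverage is exact) and
    integrated with the 2-D trapezoidal rule, which is exact for planes.
    """
    config = config or SurrogateConfig()
    cx, cy = config.roi_center
    sx, sy = config.roi_size
    xs = _grid_coords(cx - sx / 2.0, cx + sx / 2.0, config.grid_spacing)
    ys = _grid_coords(cy - sy / 2.0, cy + sy / 2.0, config.grid_spacing)
    H = _grid_heights(frame, xs, ys, config.n_nearest_lines)
    return float(np.trapezoid(np.trapezoid(H, xs, axis=1), ys))


def _extract_frame_scalar(frames, func, label) -> SurrogateTrace:
    times, values = [], []
    for frame in frames:
        try:
            values.append(func(frame))
        except (SurfaceInterpolationError, ValueError) as exc:
            logger.warning("skipping frame t=%.3f for %s: %s", frame.time, label, exc)
            continue
        times.append(frame.time)
    if not times:
        raise SurfaceInterpolationError(f"no frame usable for {label}")
    return SurrogateTrace(np.array(times), np.array(values), label=label,
                          units="mm^3" if label == "SDV" else "mm")


def extract_rdm_trace(frames: Sequence[SurfaceFrame],
                      config: SurrogateConfig | None = None) -> SurrogateTrace:
    config = config or SurrogateConfig()
    return _extract_frame_scalar(frames, lambda f: compute_rdm(f, config.rdm_origin), "RDM")


def extract_sdv_trace(frames: Sequence[SurfaceFrame],
                      config: SurrogateConfig | None = None) -> SurrogateTrace:
    config = config or SurrogateConfig()
    return _extract_frame_scalar(frames, lambda f: compute_sdv(f, config), "SDV")


def extract_all_surrogates(frames: Sequence[SurfaceFrame],
                           config: SurrogateConfig | None = None
                           ) -> Dict[str, SurrogateTrace]:
    """All four surrogate traces; RDM uses raw points, the rest fixed coordinates."""
    config = config or SurrogateConfig()
    return {
        "AP": extract_point_surrogate(frames, config.ap_location, config, label="AP"),
        "TP": extract_point_surrogate(frames, config.tp_location, config, label="TP"),
        "RDM": extract_rdm_trace(frames, config),
        "SDV": extract_sdv_trace(frames, config),
    }
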