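"""Synthetic breathing signals, deforming torso surfaces, and cine-like sampling.

The generator emulates the acquisition geometry the analysis assumes:
~8-minute sessions with a torso surface sampled as 11 laser-line polygonal
chains at 3 Hz, a latent breathing signal with cycle-to-cycle period and
amplitude variability plus slow drift, an abdomen-leads-thorax lag, and a
tumor whose position is affine in the latent signal and its time
derivative (hysteresis).  Sparse, noisy tumor observations mimic
quasi-random cine acquisitions with a finite exposure window.

Coordinate convention: x lateral, y craniocaudal (cranial positive),
z vertical (anterior positive); millimetres and seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Sequence

import numpy as np

from ._piecewise import window_mean
from .surrogates import SurfaceFrame, SurrogateTrace
from .motion_model import estimate_derivative

__all__ = [
    "BreathingParams",
    "TorsoParams",
    "GroundTruthModel",
    "CineSchedule",
    "LatentSignal",
    "Trajectory",
    "TumorObservation",
    "simulate_breathing_signal",
    "simulate_surface_sequence",
    "simulate_tumor_trajectory",
    "sample_cine_sessions",
    "observations_to_arrays",
    "default_torso",
]


@dataclass
class BreathingParams:
    """Cycle-by-cycle breathing signal parameters (latent units are mm)."""

    nominal_period: float = 4.0     # s
    period_sd: float = 0.45         # s
    nominal_amplitude: float = 7.0  # mm
    amplitude_sd: float = 1.1       # mm
    drift_rate: float = 0.35        # mm / min, additive linear drift
    noise_sd: float = 0.05          # mm, additive white sensor noise
    duration: float = 480.0         # s
    sample_rate: float = 3.0        # Hz
    rest_fraction: float = 0.5      # fraction of each cycle at full exhalation

    def validate(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.nominal_period <= 0:
            raise ValueError("nominal_period must be positive")
        if min(self.period_sd, self.amplitude_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.rest_fraction < 1:
            raise ValueError("rest_fraction must be in [0, 1)")


@dataclass
class LatentSignal:
    """Sampled latent breathing signal.

    ``values`` is what the surface sensor sees (respiratory component plus
    drift plus sensor noise); ``clean`` is the drift- and noise-free
    respiratory component that drives the tumor.
    """

    times: np.ndarray
    values: np.ndarray
    clean: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.clean = np.asarray(self.clean, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty signal")

    def __len__(self) -> int:
        return self.times.size


def simulate_breathing_signal(params: BreathingParams, seed: int) -> LatentSignal:
    """Generate an irregular breathing signal, cycle by cycle.

    Each cycle draws its own period and amplitude; within a cycle the shape
    is a raised-cosine inhalation bump followed by a rest plateau at zero
    (full exhalation), so exhalation minima are well defined for the
    baseline filter.  Drift and white noise are added on top.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(np.floor(params.duration * params.sample_rate))
    if n < 2:
        raise ValueError("duration too short for the given sample rate")
    t = np.arange(n) / params.sample_rate

    starts = [0.0]
    periods: list[float] = []
    amplitudes: list[float] = []
    while starts[-1] <= params.duration:
        T = float(rng.normal(params.nominal_period, params.period_sd))
        T = max(T, 0.3 * params.nominal_period)
        A = max(float(rng.normal(params.nominal_amplitude, params.amplitude_sd)), 0.0)
        periods.append(T)
        amplitudes.append(A)
        starts.append(starts[-1] + T)
    start_arr = np.array(starts[:-1])
    period_arr = np.array(periods)
    amp_arr = np.array(amplitudes)

    idx = np.clip(np.searchsorted(start_arr, t, side="right") - 1, 0, start_arr.size - 1)
    tau = (t - start_arr[idx]) / period_arr[idx]
    active = 1.0 - params.rest_fraction
    clean = np.where(tau < active,
                     amp_arr[idx] * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / active)),
                     0.0)
    values = clean + params.drift_rate * t / 60.0
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=n)
    return LatentSignal(times=t, values=values, clean=clean,
                        sample_rate=params.sample_rate)


def _plateau_taper(d: np.ndarray, plateau: float, support: float) -> np.ndarray:
    """1 inside `plateau`, cosine-squared taper to 0 at `support`."""
    d = np.abs(np.asarray(d, dtype=float))
    w = np.zeros_like(d)
    w[d <= plateau] = 1.0
    ramp = (d > plateau) & (d < support)
    w[ramp] = np.cos(0.5 * np.pi * (d[ramp] - plateau) / (support - plateau)) ** 2
    return w


@dataclass
class TorsoParams:
    """Static torso geometry and its breathing deformation weights.

    The surface height is ``z0(x, y) + w_ab(x, y) * v(t) + w_th(x, y) *
    v(t - thorax_lag)``; the default maps (see :func:`default_torso`)
    place a unit-weight abdominal plateau around y = -150 mm and a
    thoracic plateau around the xiphoid at y = 0.
    """

    base_height_map: Callable[[np.ndarray, np.ndarray], np.ndarray]
    abdominal_weight_map: Callable[[np.ndarray, np.ndarray], np.ndarray]
    thoracic_weight_map: Callable[[np.ndarray, np.ndarray], np.ndarray]
    thorax_lag: float = 1.0                     # s, abdomen leads thorax
    line_positions: np.ndarray = field(
        default_factory=lambda: np.linspace(-225.0, 0.0, 11))
    points_per_line: int = 45
    dropout_rate_edges: float = 0.05
    point_noise_sd: float = 0.2                  # mm, on heights
    lateral_extent: float = 150.0                # mm, half-width in x
    edge_fraction: float = 0.8                   # |x| beyond this fraction may drop out

    def validate(self) -> None:
        lp = np.asarray(self.line_positions, dtype=float)
        if lp.size < 2 or np.any(np.diff(lp) <= 0):
            raise ValueError("line_positions must be strictly increasing")
        if not 0 <= self.dropout_rate_edges < 1:
            raise ValueError("dropout_rate_edges must be in [0, 1)")
        if self.points_per_line < 2:
            raise ValueError("need at least 2 points per line")
        if self.point_noise_sd < 0 or self.thorax_lag < 0:
            raise ValueError("noise and lag must be non-negative")


def default_torso(thorax_lag: float = 1.0, points_per_line: int = 45,
                  dropout_rate_edges: float = 0.05, point_noise_sd: float = 0.2,
                  thorax_scale: float = 1.0) -> TorsoParams:
    """Default torso: gentle static dome, compact abdominal/thoracic bumps.

    The abdominal weight is exactly 1 on |y + 150| <= 30 mm (covering the
    lines nearest the abdominal monitoring point) and 0 beyond 100 mm;
    the thoracic weight is `thorax_scale` on |y| <= 60 mm and 0 beyond
    130 mm.  The supports are disjoint from the other point's nearest
    lines, so each monitored point sees a single driver.
    """

    def z0(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return 120.0 - 1.5e-3 * x**2 + 0.05 * (y + 112.5)

    def w_ab(x, y):
        return _plateau_taper(np.asarray(y, dtype=float) + 150.0, 30.0, 100.0) \
            * np.ones_like(np.asarray(x, dtype=float))

    def w_th(x, y):
        return thorax_scale * _plateau_taper(np.asarray(y, dtype=float), 60.0, 130.0) \
            * np.ones_like(np.asarray(x, dtype=float))

    return TorsoParams(base_height_map=z0, abdominal_weight_map=w_ab,
                       thoracic_weight_map=w_th, thorax_lag=thorax_lag,
                       points_per_line=points_per_line,
                       dropout_rate_edges=dropout_rate_edges,
                       point_noise_sd=point_noise_sd)


def simulate_surface_sequence(signal: LatentSignal, torso: TorsoParams,
                              seed: int) -> List[SurfaceFrame]:
    """Laser-line point-cloud frames of the deforming torso at the signal times."""
    torso.validate()
    if len(signal) == 0:
        raise ValueError("empty signal")
    rng = np.random.default_rng(seed)
    t = signal.times
    v = signal.values
    # thorax follows the abdomen with a lag; constant extrapolation at the start
    vlag = np.interp(t - torso.thorax_lag, t, v)

    x = np.linspace(-torso.lateral_extent, torso.lateral_extent, torso.points_per_line)
    ys = np.asarray(torso.line_positions, dtype=float)
    L, P, T = ys.size, x.size, t.size
    Xg, Yg = np.meshgrid(x, ys)                      # (L, P)
    z0 = np.asarray(torso.base_height_map(Xg, Yg), dtype=float)
    wab = np.asarray(torso.abdominal_weight_map(Xg, Yg), dtype=float)
    wth = np.asarray(torso.thoracic_weight_map(Xg, Yg), dtype=float)

    # (T, L, P) heights
    Z = (z0[None, :, :]
         + wab[None, :, :] * v[:, None, None]
         + wth[None, :, :] * vlag[:, None, None])
    if torso.point_noise_sd > 0:
        Z = Z + rng.normal(0.0, torso.point_noise_sd, size=Z.shape)

    edge = np.abs(x) > torso.edge_fraction * torso.lateral_extent
    keep = np.ones((T, L, P), dtype=bool)
    if torso.dropout_rate_edges > 0 and np.any(edge):
        drop = rng.random((T, L, P)) < torso.dropout_rate_edges
        keep[:, :, edge] &= ~drop[:, :, edge]

    frames: List[SurfaceFrame] = []
    for k in range(T):
        lines = {}
        for j in range(L):
            m = keep[k, j]
            pts = np.column_stack([x[m], np.full(int(m.sum()), ys[j]), Z[k, j, m]])
            lines[j] = pts
        frames.append(SurfaceFrame(time=float(t[k]), lines=lines))
    return frames


@dataclass
class GroundTruthModel:
    """Generative twin of the fitted motion model."""

    x0_true: np.ndarray = field(default_factory=lambda: np.array([2.0, -1.0, 3.0]))
    xA_true: np.ndarray = field(default_factory=lambda: np.array([0.3, -1.2, 0.5]))
    xAprime_true: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.22, 0.08]))
    obs_noise_sd: float = 0.5    # mm, isotropic registration noise
    session_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.x0_true = np.asarray(self.x0_true, dtype=float).reshape(3)
        self.xA_true = np.asarray(self.xA_true, dtype=float).reshape(3)
        self.xAprime_true = np.asarray(self.xAprime_true, dtype=float).reshape(3)
        self.session_shift = np.asarray(self.session_shift, dtype=float).reshape(3)
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be non-negative")


@dataclass
class Trajectory:
    """Continuous tumor trajectory: piecewise linear between grid samples."""

    times: np.ndarray
    positions: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.times.size != self.positions.shape[0]:
            raise ValueError("times/positions length mismatch")


@dataclass
class TumorObservation:
    time: float
    position: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)


def simulate_tumor_trajectory(signal: LatentSignal, gt: GroundTruthModel) -> Trajectory:
    """Tumor trajectory affine in the clean latent signal and its derivative.

    ``x(t) = x0 + v(t) xA + v'(t) xAprime + session_shift`` with the
    drift-free respiratory component ``v`` (baseline drift is a surface
    measurement artifact, not tumor motion) and the derivative computed by
    the same central-difference convention as the modeling stage.
    """
    if len(signal) < 3:
        raise ValueError("signal too short to differentiate")
    v = signal.clean
    vp = estimate_derivative(
        SurrogateTrace(signal.times, v, label="latent")).values
    pos = (gt.x0_true[None, :]
           + v[:, None] * gt.xA_true[None, :]
           + vp[:, None] * gt.xAprime_true[None, :]
           + gt.session_shift[None, :])
    return Trajectory(times=signal.times.copy(), positions=pos)


def sample_cine_sessions(trajectory: Trajectory, schedule: "CineSchedule",
                         seed: int, noise_sd: float = 0.0) -> List[TumorObservation]:
    """Sparse quasi-random observations of the trajectory.

    Acquisition midpoints accumulate ``mean_interval +- uniform jitter``;
    each observation is the exact mean of the (piecewise-linear) trajectory
    over its exposure window plus isotropic Gaussian registration noise,
    timestamped at the window midpoint.
    """
    schedule.validate()
    rng = np.random.default_rng(seed)
    jit = rng.uniform(-schedule.interval_jitter, schedule.interval_jitter,
                      size=schedule.n_acquisitions) if schedule.interval_jitter > 0 \
        else np.zeros(schedule.n_acquisitions)
    mids = np.cumsum(schedule.mean_interval + jit)
    half = schedule.exposure / 2.0
    t = trajectory.times
    if mids[0] - half < t[0] or mids[-1] + half > t[-1]:
        raise ValueError("cine schedule exceeds the trajectory span")
    obs_pos = np.column_stack([
        window_mean(t, trajectory.positions[:, c], mids, schedule.exposure)
        for c in range(3)
    ])
    if noise_sd > 0:
        obs_pos = obs_pos + rng.normal(0.0, noise_sd, size=obs_pos.shape)
    return [TumorObservation(time=float(m), position=p) for m, p in zip(mids, obs_pos)]


def observations_to_arrays(obs: Sequence[TumorObservation]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([o.time for o in obs])
    positions = np.array([o.position for o in obs])
    return times, positions


@dataclass
class CineSchedule:
    n_acquisitions: int = 100
    mean_interval: float = 4.6   # s (about one acquisition every 5th second)
    interval_jitter: float = 1.5  # s, uniform
    exposure: float = 0.3         # s

    def validate(self) -> None:
        if self.n_acquisitions < 1:
            raise ValueError("n_acquisitions must be >= 1")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.mean_interval <= self.exposure:
            raise ValueError("mean_interval must exceed the exposure")
        if not 0 <= self.interval_jitter < self.mean_interval - self.exposure / 2:
            raise ValueError("interval_jitter too large for the mean interval")
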