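"""Study orchestration: simulate sessions, compare surrogates and methods,
sweep training-set sizes, and project trajectories onto principal axes.

The study design mirrors a planning session followed by two treatment
fractions: session 1 is the training set, sessions 2 and 3 are pooled for
validation.  Part 1 compares the four surrogates (plus the phase-method
comparator on the abdominal point); part 2 sweeps the number of
chronologically-first training acquisitions for the winning surrogate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import baseline as bl
from . import motion_model as mm
from . import phase_method as pm
from . import surrogates as sg
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "StudySession",
    "StudyDataset",
    "ComparisonTable",
    "SweepResult",
    "PrincipalAxes",
    "default_scenario",
    "simulate_study",
    "run_surrogate_comparison",
    "compare_methods",
    "run_training_size_sweep",
    "project_principal_axes",
    "compute_modeled_measured_correlation",
]

SURROGATES = ("AP", "RDM", "SDV", "TP")


@dataclass
class Scenario:
    """Everything needed to generate one three-session synthetic study."""

    breathing: syn.BreathingParams = field(default_factory=syn.BreathingParams)
    torso: syn.TorsoParams = field(default_factory=syn.default_torso)
    ground_truth: syn.GroundTruthModel = field(default_factory=syn.GroundTruthModel)
    schedule: syn.CineSchedule = field(default_factory=syn.CineSchedule)
    surrogate_config: sg.SurrogateConfig = field(default_factory=sg.SurrogateConfig)
    n_sessions: int = 3
    session_shifts: Sequence[np.ndarray] | None = None
    center_observations: bool = True


def default_scenario(duration: float = 500.0, n_acquisitions: int = 100,
                     points_per_line: int = 45, **overrides) -> Scenario:
    """The default synthetic scenario: irregular abdominal-driven breathing,
    lagging thorax, measurement noise, ~8-minute sessions, 100 cine samples.

    Keyword overrides are applied to the breathing parameters when their
    name matches a ``BreathingParams`` field, otherwise to the scenario.
    """
    breathing = syn.BreathingParams(duration=duration)
    scen_kwargs = {}
    for key, val in overrides.items():
        if hasattr(breathing, key):
            setattr(breathing, key, val)
        else:
            scen_kwargs[key] = val
    torso = syn.default_torso(points_per_line=points_per_line)
    schedule = syn.CineSchedule(n_acquisitions=n_acquisitions, mean_interval=4.5,
                                interval_jitter=1.5, exposure=0.3)
    return Scenario(breathing=breathing, torso=torso, schedule=schedule, **scen_kwargs)


class StudySession:
    """One simulated session with lazily extracted surrogate samples."""

    def __init__(self, session_id: int, scenario: Scenario, signal, frames,
                 trajectory, obs_times, obs_positions_raw):
        self.session_id = session_id
        self.scenario = scenario
        self.signal = signal
        self.frames = frames
        self.trajectory = trajectory
        self.obs_times = obs_times
        self.obs_positions_raw = obs_positions_raw
        self.obs_positions = (mm.center_positions(obs_positions_raw)
                              if scenario.center_observations
                              else obs_positions_raw.copy())
        self._traces: Dict[str, sg.SurrogateTrace] = {}
        self._corrected: Dict[str, sg.SurrogateTrace] = {}
        self._segs: Dict[str, bl.CycleSegmentation] = {}
        self._samples: Dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- surrogate pipeline, cached per label ------------------------------
    def raw_trace(self, label: str) -> sg.SurrogateTrace:
        if label not in self._traces:
            cfg = self.scenario.surrogate_config
            if label == "AP":
                tr = sg.extract_point_surrogate(self.frames, cfg.ap_location, cfg, "AP")
            elif label == "TP":
                tr = sg.extract_point_surrogate(self.frames, cfg.tp_location, cfg, "TP")
            elif label == "RDM":
                tr = sg.extract_rdm_trace(self.frames, cfg)
            elif label == "SDV":
                tr = sg.extract_sdv_trace(self.frames, cfg)
            else:
                raise ValueError(f"unknown surrogate {label!r}")
            self._traces[label] = tr
        return self._traces[label]

    def segmentation(self, label: str) -> bl.CycleSegmentation:
        if label not in self._segs:
            self._segs[label] = bl.detect_exhalation_extrema(self.raw_trace(label))
        return self._segs[label]

    def corrected_trace(self, label: str) -> sg.SurrogateTrace:
        if label not in self._corrected:
            seg = self.segmentation(label)
            base = bl.compute_baseline(self.raw_trace(label), seg)
            self._corrected[label] = bl.baseline_correct(self.raw_trace(label), base)
        return self._corrected[label]

    def surrogate_samples(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Exposure-averaged (A, A') at the cine acquisition times."""
        if label not in self._samples:
            cfg = self.scenario.surrogate_config
            trace = self.corrected_trace(label)
            deriv = mm.estimate_derivative(trace)
            self._samples[label] = mm.sample_surrogate_at(
                trace, deriv, self.obs_times, self.scenario.schedule.exposure,
                max_gap=cfg.max_gap_s)
        return self._samples[label]

    def training_set(self, label: str, centered: bool = True) -> mm.TrainingSet:
        A, Ap = self.surrogate_samples(label)
        x = self.obs_positions if centered else self.obs_positions_raw
        return mm.TrainingSet(A=A, Aprime=Ap, x=x, times=self.obs_times)

    def phases(self, label: str = "AP") -> tuple[np.ndarray, np.ndarray]:
        """Breathing phases at the cine times that fall between detected minima.

        Returns (phases, index of usable observations); out-of-range
        acquisitions (before the first / after the last minimum) are dropped.
        """
        seg = self.segmentation(label)
        m = seg.minima_times
        ok = (self.obs_times >= m[0]) & (self.obs_times <= m[-1])
        if not np.all(ok):
            logger.info("session %d: %d acquisitions outside phase coverage",
                        self.session_id, int((~ok).sum()))
        ph = pm.compute_phase(self.corrected_trace(label), seg, self.obs_times[ok])
        return ph, np.flatnonzero(ok)


@dataclass
class StudyDataset:
    sessions: List[StudySession]
    scenario: Scenario
    seed: int

    @property
    def training_session(self) -> StudySession:
        return self.sessions[0]

    @property
    def validation_sessions(self) -> List[StudySession]:
        return self.sessions[1:]


def _session_seeds(seed: int, n_sessions: int) -> list[tuple[int, int, int]]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 * n_sessions)
    ints = [int(c.generate_state(1)[0]) for c in children]
    return [tuple(ints[3 * s:3 * s + 3]) for s in range(n_sessions)]


def simulate_study(scenario: Scenario, seed: int) -> StudyDataset:
    """Generate `n_sessions` sessions sharing one ground-truth model.

    Sessions draw independent breathing signals (and noise) from seeds
    derived deterministically from `seed`; session 1 is the training
    session, the rest validate.
    """
    sessions = []
    for s, (seed_sig, seed_surf, seed_cine) in enumerate(
            _session_seeds(seed, scenario.n_sessions)):
        gt = scenario.ground_truth
        if scenario.session_shifts is not None:
            gt = dataclasses.replace(
                gt, session_shift=np.asarray(scenario.session_shifts[s], dtype=float))
        signal = syn.simulate_breathing_signal(scenario.breathing, seed_sig)
        frames = syn.simulate_surface_sequence(signal, scenario.torso, seed_surf)
        trajectory = syn.simulate_tumor_trajectory(signal, gt)
        obs = syn.sample_cine_sessions(trajectory, scenario.schedule, seed_cine,
                                       noise_sd=gt.obs_noise_sd)
        obs_t, obs_x = syn.observations_to_arrays(obs)
        sessions.append(StudySession(s + 1, scenario, signal, frames,
                                     trajectory, obs_t, obs_x))
    return StudyDataset(sessions=sessions, scenario=scenario, seed=seed)


# ---------------------------------------------------------------------------
# part 1: surrogate comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Rows of (method, surrogate, eps_mean, eps_p90, n) pooled over
    the validation sessions, plus optional per-session breakdowns."""

    table: pd.DataFrame
    per_session: pd.DataFrame | None = None

    def winner(self) -> str:
        """Surrogate with the smallest mean residual (p90 breaks ties)."""
        low = self.table[self.table["method"] == "low"]
        row = low.sort_values(["eps_mean", "eps_p90"]).iloc[0]
        return str(row["surrogate"])


def _pooled_validation(dataset: StudyDataset, label: str) -> mm.TrainingSet:
    parts = [s.training_set(label) for s in dataset.validation_sessions]
    return mm.TrainingSet(
        A=np.concatenate([p.A for p in parts]),
        Aprime=np.concatenate([p.Aprime for p in parts]),
        x=np.concatenate([p.x for p in parts]),
        times=np.concatenate([p.times for p in parts]),
    )


def run_surrogate_comparison(dataset: StudyDataset,
                             surrogates: Sequence[str] = SURROGATES,
                             n_bins: int = 10) -> ComparisonTable:
    """Train on session 1, validate pooled on sessions 2+3 for every
    surrogate; add a phase-method row on the abdominal point."""
    if len(dataset.sessions) < 2:
        raise ValueError("need at least one validation session")
    rows, per_rows = [], []
    for label in surrogates:
        try:
            params = mm.fit_low_model(dataset.training_session.training_set(label),
                                      surrogate=label)
        except Exception as exc:
            raise RuntimeError(f"fit stage failed for surrogate {label}: {exc}") from exc
        summary = mm.compute_residuals(params, _pooled_validation(dataset, label))
        rows.append(("low", label, summary.mean, summary.p90, summary.n))
        for sess in dataset.validation_sessions:
            s = mm.compute_residuals(params, sess.training_set(label))
            per_rows.append(("low", label, sess.session_id, s.mean, s.p90, s.n))

    # phase-method comparator on AP
    train = dataset.training_session
    ph, idx = train.phases("AP")
    table = pm.build_phase_bins(ph, train.obs_positions[idx], n_bins=n_bins)
    vec = []
    for sess in dataset.validation_sessions:
        ph_v, idx_v = sess.phases("AP")
        modeled = table.lookup(ph_v)
        vec.append(modeled - sess.obs_positions[idx_v])
    summary = mm.summarize_residuals(np.concatenate(vec))
    rows.append(("phase", "AP", summary.mean, summary.p90, summary.n))

    cols = ["method", "surrogate", "eps_mean", "eps_p90", "n"]
    per_cols = ["method", "surrogate", "session", "eps_mean", "eps_p90", "n"]
    return ComparisonTable(table=pd.DataFrame(rows, columns=cols),
                           per_session=pd.DataFrame(per_rows, columns=per_cols))


def compare_methods(dataset: StudyDataset, label: str = "AP",
                    n_bins: int = 10) -> Dict[str, float]:
    """Mean validation residual of the full model, the amplitude-only
    reduction, and the phase method, on the same dataset and split."""
    train = dataset.training_session.training_set(label)
    val = _pooled_validation(dataset, label)
    full = mm.compute_residuals(mm.fit_low_model(train, surrogate=label), val)
    amp = mm.compute_residuals(mm.fit_amplitude_only(train, surrogate=label), val)
    tr = dataset.training_session
    ph, idx = tr.phases(label)
    table = pm.build_phase_bins(ph, tr.obs_positions[idx], n_bins=n_bins)
    vec = []
    for sess in dataset.validation_sessions:
        ph_v, idx_v = sess.phases(label)
        vec.append(table.lookup(ph_v) - sess.obs_positions[idx_v])
    phase = mm.summarize_residuals(np.concatenate(vec))
    return {"low": full.mean, "amplitude_only": amp.mean, "phase": phase.mean,
            "low_p90": full.p90, "amplitude_only_p90": amp.p90, "phase_p90": phase.p90}


# ---------------------------------------------------------------------------
# part 2: training-size sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    sizes: np.ndarray
    per_replicate: pd.DataFrame        # replicate, n, eps_mean, eps_p90
    median_curve: pd.DataFrame         # n, eps_p90_median, eps_mean_median

    def median_p90(self, n: int) -> float:
        row = self.median_curve[self.median_curve["n"] == n]
        return float(row["eps_p90_median"].iloc[0])


def training_size_curve(dataset: StudyDataset, sizes: Sequence[int],
                        label: str = "AP") -> pd.DataFrame:
    """Fit on the first n chronological training acquisitions, validate pooled."""
    sizes = list(sizes)
    if any(n < 4 for n in sizes):
        raise ValueError("training sizes below 4 are rejected")
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be increasing")
    train_full = dataset.training_session.training_set(label)
    if max(sizes) > len(train_full):
        raise ValueError(f"largest size {max(sizes)} exceeds the "
                         f"{len(train_full)} training acquisitions")
    order = np.argsort(train_full.times)
    val = _pooled_validation(dataset, label)
    rows = []
    for n in sizes:
        params = mm.fit_low_model(train_full.subset(order[:n]), surrogate=label)
        summary = mm.compute_residuals(params, val)
        rows.append((n, summary.mean, summary.p90))
    return pd.DataFrame(rows, columns=["n", "eps_mean", "eps_p90"])


def run_training_size_sweep(scenario: Scenario, sizes: Sequence[int],
                            replicates: int, seed: int,
                            label: str = "AP") -> SweepResult:
    """Replicate the training-size curve over independently seeded datasets."""
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(replicates)]
    frames = []
    for r, rep_seed in enumerate(rep_seeds):
        dataset = simulate_study(scenario, rep_seed)
        curve = training_size_curve(dataset, sizes, label=label)
        curve.insert(0, "replicate", r)
        frames.append(curve)
    per_rep = pd.concat(frames, ignore_index=True)
    med = (per_rep.groupby("n")
           .agg(eps_p90_median=("eps_p90", "median"),
                eps_mean_median=("eps_mean", "median"))
           .reset_index())
    return SweepResult(sizes=np.asarray(list(sizes)), per_replicate=per_rep,
                       median_curve=med)


# ---------------------------------------------------------------------------
# principal axes and correlation
# ---------------------------------------------------------------------------

@dataclass
class PrincipalAxes:
    mean: np.ndarray        # (3,)
    axes: np.ndarray        # (3, 3), rows = axes, decreasing variance
    variances: np.ndarray   # (3,)
    scores: np.ndarray      # (n, 3) rotated, mean-centered coordinates


def project_principal_axes(positions) -> PrincipalAxes:
    """Mean-centered coordinates in the orthonormal eigenbasis of the
    position covariance, ordered by decreasing variance.

    Sign convention: each axis is flipped so its largest-magnitude
    component is positive, making the rotation deterministic.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    mean = pos.mean(axis=0)
    centered = pos - mean
    cov = centered.T @ centered / max(pos.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    scores = centered @ axes.T
    if pos.shape[0] < 3 or np.linalg.matrix_rank(centered) < 2:
        logger.info("principal axes from rank-deficient positions")
    return PrincipalAxes(mean=mean, axes=axes, variances=np.maximum(evals, 0.0),
                         scores=scores)


def compute_modeled_measured_correlation(modeled, measured) -> np.ndarray:
    """Pearson correlation of modeled vs measured position along each
    principal axis of the *measured* positions.

    Axes on which either projection has zero variance yield NaN (flagged
    in the log) rather than a silent 0.
    """
    modeled = np.asarray(modeled, dtype=float).reshape(-1, 3)
    measured = np.asarray(measured, dtype=float).reshape(-1, 3)
    if modeled.shape != measured.shape or measured.shape[0] < 3:
        raise ValueError("need >= 3 matched position pairs")
    pa = project_principal_axes(measured)
    meas_s = pa.scores
    mod_s = (modeled - pa.mean) @ pa.axes.T
    out = np.empty(3)
    for i in range(3):
        a, b = mod_s[:, i], meas_s[:, i]
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            logger.warning("axis %d has zero variance; correlation undefined", i + 1)
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(a, b)[0, 1]
    return out
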