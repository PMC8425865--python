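"""Validated YAML configuration for the study pipeline.

The config file is a single YAML document with optional sections
``breathing``, ``torso``, ``ground_truth``, ``schedule``, ``surrogate``
and ``study``; every field has a default, so an empty file is valid.
Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import experiments as ex
from . import surrogates as sg
from . import synthetic as syn


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BreathingSection(_Strict):
    nominal_period: float = 4.0
    period_sd: float = Field(0.45, ge=0)
    nominal_amplitude: float = 7.0
    amplitude_sd: float = Field(1.1, ge=0)
    drift_rate: float = 0.35
    noise_sd: float = Field(0.05, ge=0)
    duration: float = Field(500.0, gt=0)
    sample_rate: float = Field(3.0, gt=0)
    rest_fraction: float = Field(0.5, ge=0, lt=1)


class TorsoSection(_Strict):
    thorax_lag: float = Field(1.0, ge=0)
    points_per_line: int = Field(45, ge=2)
    dropout_rate_edges: float = Field(0.05, ge=0, lt=1)
    point_noise_sd: float = Field(0.2, ge=0)
    thorax_scale: float = 1.0


class GroundTruthSection(_Strict):
    x0: Tuple[float, float, float] = (2.0, -1.0, 3.0)
    xA: Tuple[float, float, float] = (0.3, -1.2, 0.5)
    xAprime: Tuple[float, float, float] = (0.05, 0.22, 0.08)
    obs_noise_sd: float = Field(0.5, ge=0)


class ScheduleSection(_Strict):
    n_acquisitions: int = Field(100, ge=1)
    mean_interval: float = Field(4.5, gt=0)
    interval_jitter: float = Field(1.5, ge=0)
    exposure: float = Field(0.3, gt=0)


class SurrogateSection(_Strict):
    ap_location: Tuple[float, float] = (0.0, -150.0)
    tp_location: Tuple[float, float] = (0.0, 0.0)
    roi_center: Tuple[float, float] = (0.0, -112.5)
    roi_size: Tuple[float, float] = (150.0, 150.0)
    grid_spacing: float = Field(20.0, gt=0)
    n_nearest_lines: int = Field(3, ge=2)


class StudySection(_Strict):
    n_sessions: int = Field(3, ge=1)
    n_phase_bins: int = Field(10, ge=1)
    sweep_sizes: list[int] = Field(
        default_factory=lambda: [4, 6, 8, 10, 14, 20, 30, 50, 70, 100])
    sweep_replicates: int = Field(20, ge=1)


class StudyConfig(_Strict):
    breathing: BreathingSection = Field(default_factory=BreathingSection)
    torso: TorsoSection = Field(default_factory=TorsoSection)
    ground_truth: GroundTruthSection = Field(default_factory=GroundTruthSection)
    schedule: ScheduleSection = Field(default_factory=ScheduleSection)
    surrogate: SurrogateSection = Field(default_factory=SurrogateSection)
    study: StudySection = Field(default_factory=StudySection)

    def to_scenario(self) -> ex.Scenario:
        b = self.breathing
        breathing = syn.BreathingParams(**b.model_dump())
        t = self.torso
        torso = syn.default_torso(thorax_lag=t.thorax_lag,
                                  points_per_line=t.points_per_line,
                                  dropout_rate_edges=t.dropout_rate_edges,
                                  point_noise_sd=t.point_noise_sd,
                                  thorax_scale=t.thorax_scale)
        g = self.ground_truth
        gt = syn.GroundTruthModel(x0_true=np.array(g.x0), xA_true=np.array(g.xA),
                                  xAprime_true=np.array(g.xAprime),
                                  obs_noise_sd=g.obs_noise_sd)
        schedule = syn.CineSchedule(**self.schedule.model_dump())
        surrogate = sg.SurrogateConfig(**self.surrogate.model_dump())
        return ex.Scenario(breathing=breathing, torso=torso, ground_truth=gt,
                           schedule=schedule, surrogate_config=surrogate,
                           n_sessions=self.study.n_sessions)


def load_config(path: Optional[str | Path] = None) -> tuple[StudyConfig, str]:
    """Load and validate a YAML config; returns (config, raw text)."""
    if path is None:
        return StudyConfig(), ""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return StudyConfig.model_validate(data), text
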