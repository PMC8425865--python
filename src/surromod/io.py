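"""Plain-text serialization of frames, traces, observations and results.

All formats are small CSV/JSON files:

* frames:        time_s, line_id, x_mm, y_mm, z_mm
* observations:  time_s, dx_mm, dy_mm, dz_mm
* traces:        time_s, value, label, baseline_corrected
* segmentation:  time_s, value, kind
* model params:  JSON with named 3-vectors, surrogate label, and units
* bin table:     bin_index, phase_lo, phase_hi, x_mm, y_mm, z_mm, count
* manifest:      JSON with seed, config hash, and library versions
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .baseline import CycleSegmentation
from .motion_model import MotionModelParams
from .phase_method import PhaseBinTable
from .surrogates import SurfaceFrame, SurrogateTrace
from .synthetic import TumorObservation

__all__ = [
    "write_frames_csv", "read_frames_csv",
    "write_observations_csv", "read_observations_csv",
    "write_trace_csv", "read_trace_csv",
    "write_segmentation_csv",
    "write_params_json", "read_params_json",
    "write_bin_table_csv",
    "write_manifest",
]


def write_frames_csv(path, frames: Sequence[SurfaceFrame]) -> None:
    recs = []
    for frame in frames:
        for lid, pts in frame.lines.items():
            for x, y, z in pts:
                recs.append((frame.time, lid, x, y, z))
    df = pd.DataFrame(recs, columns=["time_s", "line_id", "x_mm", "y_mm", "z_mm"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_frames_csv(path) -> List[SurfaceFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    frames = []
    for t, group in df.groupby("time_s", sort=True):
        lines = {int(lid): sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
                 for lid, sub in group.groupby("line_id")}
        frames.append(SurfaceFrame(time=float(t), lines=lines))
    return frames


def write_observations_csv(path, obs: Sequence[TumorObservation]) -> None:
    df = pd.DataFrame(
        [(o.time, *o.position) for o in obs],
        columns=["time_s", "dx_mm", "dy_mm", "dz_mm"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_observations_csv(path) -> List[TumorObservation]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [TumorObservation(time=float(r.time_s),
                             position=np.array([r.dx_mm, r.dy_mm, r.dz_mm]))
            for r in df.itertuples()]


def write_trace_csv(path, trace: SurrogateTrace) -> None:
    pd.DataFrame({
        "time_s": trace.times,
        "value": trace.values,
        "label": trace.label,
        "baseline_corrected": trace.baseline_corrected,
    }).to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path) -> SurrogateTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    label = str(df["label"].iloc[0])
    return SurrogateTrace(times=df["time_s"].to_numpy(dtype=float),
                          values=df["value"].to_numpy(dtype=float),
                          label=label,
                          baseline_corrected=bool(df["baseline_corrected"].iloc[0]),
                          units="mm^3" if label == "SDV" else "mm")


def write_segmentation_csv(path, seg: CycleSegmentation) -> None:
    pd.DataFrame({
        "time_s": seg.minima_times,
        "value": seg.minima_values,
        "kind": "minimum",
    }).to_csv(path, index=False)


def write_params_json(path, params: MotionModelParams, units: str = "mm") -> None:
    Path(path).write_text(json.dumps({
        "surrogate": params.surrogate,
        "units": units,
        "x0_mm": params.x0.tolist(),
        "xA_mm_per_unit": params.xA.tolist(),
        "xAprime_mm_s_per_unit": params.xAprime.tolist(),
    }, indent=2))


def read_params_json(path) -> MotionModelParams:
    d = json.loads(Path(path).read_text())
    return MotionModelParams(x0=np.array(d["x0_mm"]),
                             xA=np.array(d["xA_mm_per_unit"]),
                             xAprime=np.array(d["xAprime_mm_s_per_unit"]),
                             surrogate=d.get("surrogate"))


def write_bin_table_csv(path, table: PhaseBinTable) -> None:
    width = 1.0 / table.n_bins
    pd.DataFrame({
        "bin_index": np.arange(table.n_bins),
        "phase_lo": np.arange(table.n_bins) * width,
        "phase_hi": (np.arange(table.n_bins) + 1) * width,
        "x_mm": table.bin_positions[:, 0],
        "y_mm": table.bin_positions[:, 1],
        "z_mm": table.bin_positions[:, 2],
        "count": table.bin_counts,
    }).to_csv(path, index=False)


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()[:16]


def write_manifest(path, seed: int, config_text: str = "", extra: dict | None = None) -> None:
    import scipy

    from . import __version__
    manifest = {
        "seed": seed,
        "config_sha256_16": config_hash(config_text),
        "surromod_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
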