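import dataclasses

import numpy as np
import pytest

import surromod.experiments as ex
import surromod.synthetic as syn
from surromod.surrogates import SurfaceFrame


def make_frame(time=0.0, line_ys=(-40.0, -20.0, 0.0), xs=None, height=None):
    """Frame with one point row per line; `height` maps (x, y) -> z."""
    if xs is None:
        xs = np.linspace(-50.0, 50.0, 11)
    if height is None:
        height = lambda x, y: np.full_like(np.asarray(x, dtype=float), 100.0)
    lines = {}
    for i, y in enumerate(line_ys):
        z = height(np.asarray(xs, dtype=float), y)
        lines[i] = np.column_stack([xs, np.full(len(xs), y), z])
    return SurfaceFrame(time=time, lines=lines)


def roi_frame(height=None, time=0.0):
    """Frame whose lines comfortably cover the default SDV ROI."""
    return make_frame(time=time, line_ys=np.linspace(-225.0, 0.0, 11),
                      xs=np.linspace(-150.0, 150.0, 31), height=height)


def fast_scenario(duration=150.0, n_acquisitions=30, points_per_line=30, **kw):
    return ex.default_scenario(duration=duration, n_acquisitions=n_acquisitions,
                               points_per_line=points_per_line, **kw)


def noiseless_scenario(duration=150.0, n_acquisitions=30, points_per_line=30,
                       thorax_lag=1.0):
    scen = fast_scenario(duration=duration, n_acquisitions=n_acquisitions,
                         points_per_line=points_per_line,
                         noise_sd=0.0, drift_rate=0.0)
    scen.torso = syn.default_torso(thorax_lag=thorax_lag,
                                   points_per_line=points_per_line,
                                   dropout_rate_edges=0.0, point_noise_sd=0.0)
    scen.ground_truth = dataclasses.replace(scen.ground_truth, obs_noise_sd=0.0)
    return scen


@pytest.fixture(scope="session")
def default_dataset():
    """One realistic (noisy) small study shared across read-only tests."""
    return ex.simulate_study(fast_scenario(), seed=1234)


@pytest.fixture(scope="session")
def noiseless_dataset():
    scen = noiseless_scenario()
    scen.center_observations = False
    return ex.simulate_study(scen, seed=77)
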