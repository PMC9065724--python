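import warnings

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from beeland.kinematics import StateSeries, accel_from_rdot, differentiate
from beeland.trajio import FS_HZ, LandingMetadata, Trajectory

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*[Cc]onverg.*")

META = LandingMetadata("twilight", "checkerboard", "free_flight", 0, 1, "hive")


def states_from_r(r, t=None, y0=0.5, track_id="fixture", noise_sd=0.0, rng=None):
    """Build a kinematically consistent StateSeries from an r(t) profile.

    y integrates dy/dt = -r y from y0; optional white noise of sd
    ``noise_sd`` is added to r (V follows as r_noisy * y, so states.r
    carries exactly that noise).
    """
    r = np.asarray(r, float)
    if t is None:
        t = np.arange(len(r)) / FS_HZ
    y = y0 * np.exp(-cumulative_trapezoid(r, t, initial=0.0))
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        r = r + rng.normal(0.0, noise_sd, r.shape)
    V = r * y
    A = accel_from_rdot(differentiate(r, t), y, V)
    return StateSeries(track_id, t, y, V, A, r, META)


@pytest.fixture
def meta():
    return META


@pytest.fixture
def simple_track():
    """Straight-in approach at constant speed, 175 Hz, 1 s."""
    t = np.arange(0, 1.0, 1.0 / FS_HZ)
    y = 0.4 - 0.3 * t
    pos = np.column_stack([np.zeros_like(t), y, np.zeros_like(t)])
    return Trajectory("straight", t, pos, META)
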