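import numpy as np
import pytest

from cellpeer.tracks import Trajectory


def make_track(x, y, video_id="v0", track_id=0, dt=1.0):
    n = len(x)
    return Trajectory(video_id, track_id, np.arange(n), np.asarray(x, float),
                      np.asarray(y, float), dt=dt)


@pytest.fixture
def circle_track():
    """Circle of radius 10 traversed at 0.1 rad/frame, 500 points."""
    t = np.arange(500)
    return make_track(10 * np.cos(0.1 * t), 10 * np.sin(0.1 * t))


@pytest.fixture
def uniform_track():
    """Uniform motion along +x at 1 px/min, 100 points."""
    t = np.arange(100, dtype=float)
    return make_track(t, np.zeros_like(t))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
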