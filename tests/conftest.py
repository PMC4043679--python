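import numpy as np
import pytest

from qdspt.core import PIXELS, AcquisitionMeta, Trajectory, TrackSet


@pytest.fixture
def meta():
    """Reference acquisition: 25 Hz, 107 nm pixels, 25 nm precision."""
    return AcquisitionMeta(frame_interval=0.040, pixel_size=0.107,
                           localization_precision=0.025)


@pytest.fixture
def unit_meta():
    """Unit pixel size so pixel paths double as µm paths in hand examples."""
    return AcquisitionMeta(frame_interval=0.040, pixel_size=1.0)


def make_traj(id, xy, frames=None, channel="", unit=PIXELS):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(id=id, frames=frames, xy=xy, channel=channel, unit=unit)


@pytest.fixture
def make_trackset(meta):
    def _make(trajectories, condition=""):
        return TrackSet(list(trajectories), meta, condition)
    return _make


@pytest.fixture
def random_trackset(meta):
    """100 short random-walk trajectories across two channels, in pixels."""
    rng = np.random.default_rng(99)
    trajs = []
    for i in range(100):
        n = int(rng.integers(5, 30))
        xy = np.cumsum(rng.normal(0, 0.5, size=(n, 2)), axis=0) + \
            rng.uniform(0, 50, size=2)
        trajs.append(make_traj(f"t{i:03d}", xy,
                               channel="QD605" if i % 2 else "QD655"))
    return TrackSet(trajs, meta)


PT_FIXTURE = """\
%% Trajectory 1
0 10.25 3.5
1 10.5 3.75
2 10.75 4.0
%% Trajectory 2
5 20.0 21.0
6 20.1 21.2
7 20.3 21.1
"""


@pytest.fixture
def pt_text():
    return PT_FIXTURE
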