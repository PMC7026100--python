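import numpy as np
import pytest

from dyadkit.tracking import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_trajectory(x, y, visible=None, fps=25.0, frames=None):
    x = np.asarray(x, dtype=float)
    if visible is None:
        visible = np.ones(len(x), dtype=bool)
    visible = np.asarray(visible, dtype=bool)
    x = np.where(visible, x, np.nan)
    y = np.where(visible, np.asarray(y, dtype=float), np.nan)
    if frames is None:
        frames = np.arange(len(x))
    return Trajectory(fps=fps, frames=frames, x=x, y=y, visible=visible)


@pytest.fixture
def make_traj():
    return build_trajectory
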