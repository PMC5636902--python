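import numpy as np
import pytest

from femwalk import Trajectory, trial_rng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_walk_2d(rng):
    """A 2-D Gaussian random walk of 400 samples at 500 Hz."""
    return Trajectory(np.cumsum(rng.normal(0, 1, (400, 2)), axis=0), dt=0.002)


@pytest.fixture
def linear_trajectory():
    """x_i = i in both components (one unit per sample)."""
    i = np.arange(50, dtype=float)
    return Trajectory(np.column_stack([i, i]), dt=0.002)
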