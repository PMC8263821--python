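import numpy as np
import pytest

from bcrwalk.core import BCRParams, Trajectory
from bcrwalk import simulator

#: Printed parameter rows used as generative ground truth in tests.
DEER1 = BCRParams(p_i=0.01, p_s=2.01, p_f=0.01, mu=2.94, sigma=1.01,
                  x_f=(0.0, 0.0), d_min=10.0)
DEER5 = BCRParams(p_i=0.22, p_s=1.66, p_f=0.24, mu=3.03, sigma=1.06,
                  x_f=(0.0, 0.0), d_min=10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_track():
    """Four fixes on the corners of a square, 10-minute steps."""
    return Trajectory.from_positions([(0, 0), (0, 2), (2, 0), (2, 2)])


@pytest.fixture(scope="session")
def diffusion_track():
    """A pure-diffusion walk, long enough for distributional checks."""
    params = BCRParams(p_i=0.0, p_s=0.0, p_f=0.0, mu=3.0, sigma=1.0,
                       x_f=(0.0, 0.0), d_min=0.0)
    return simulator.simulate(params, 30_000, rng_seed=7)


@pytest.fixture(scope="session")
def deer5_track():
    """A medium-length walk from the fifth printed parameter row."""
    params = BCRParams(p_i=0.22, p_s=1.66, p_f=0.24, mu=3.03, sigma=1.06,
                       x_f=(0.0, 0.0), d_min=0.0)
    return simulator.simulate(params, 50_000, rng_seed=21)
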