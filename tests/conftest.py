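import numpy as np
import pytest

import flocksir as fs


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def small_params():
    """A small disordered-regime system for fast unit tests."""
    return fs.ModelParams.from_dimensionless(Pe=32, g=1, N=100)


def make_state(positions, headings=None, L=None):
    """Particle state from explicit positions (headings default to 0)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if headings is None:
        headings = np.zeros(pos.shape[0])
    return fs.ParticleState(pos, np.asarray(headings, dtype=float))


@pytest.fixture
def isolated_params():
    """Huge box: no agent ever meets another (interaction-free motion)."""
    return fs.ModelParams(
        N=4, v0=0.2, r_int=1.0, sigma=0.05, tau=1e9, L=1e4, dt=0.1
    )
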