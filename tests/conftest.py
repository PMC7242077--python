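import numpy as np
import pytest
from hypothesis import settings

from leaftracer.simulate import SimulationConfig

settings.register_profile("repro", derandomize=True, print_blob=False)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def config():
    """Default study conditions with a fixed seed."""
    return SimulationConfig(seed=7)


def forward_convolve(true, r):
    """Independent oracle for the M+1 derivatisation artifact.

    Shifts fraction r of each isotopologue's signal up one mass unit; signal
    shifted past the acquisition window is dropped.
    """
    true = np.asarray(true, dtype=float)
    obs = (1.0 - r) * true
    obs[1:] += r * true[:-1]
    return obs
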