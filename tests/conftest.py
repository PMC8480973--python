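import numpy as np
import pytest

from delaystand.controller import ControllerParams, run_closed_loop
from delaystand.plant import LimitConfig, PendulumParams


@pytest.fixture(scope="session")
def plant200():
    """Decimated-rate plant for fast closed-loop tests."""
    return PendulumParams(fs=200.0)


@pytest.fixture(scope="session")
def plant500():
    return PendulumParams(fs=500.0)


@pytest.fixture(scope="session")
def limits():
    return LimitConfig()


@pytest.fixture(scope="session")
def baseline_trial(plant500, limits):
    """One 60 s baseline (20 ms imposed delay) closed-loop trial."""
    ctrl = ControllerParams(seed=42)
    return run_closed_loop(plant500, limits, ctrl, 20.0, 60.0, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
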