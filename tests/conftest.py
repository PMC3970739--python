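import logging

import numpy as np
import pytest

from oscillometry import MechConfig, simulate_mechanics, segment_breaths, breath_table

logging.getLogger("oscillometry").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rei_config():
    """Single-compartment R-E-I system with no stochastic tone: the exact
    recovery oracle (true Z(f) known analytically)."""
    return MechConfig(R0=2.5, E=10.0, I=0.01, tone_sd=0.0, vol_gain=0.0,
                     di_time=None, duration=60.0)


@pytest.fixture(scope="session")
def rei_signal(rei_config):
    return simulate_mechanics(rei_config, seed=1)


@pytest.fixture(scope="session")
def rei_breaths(rei_signal):
    return breath_table(rei_signal, segment_breaths(rei_signal))


@pytest.fixture(scope="session")
def realistic_signal():
    """Default-parameter recording (negative X5, stochastic tone, no DI)."""
    cfg = MechConfig(di_time=None, duration=120.0)
    return simulate_mechanics(cfg, seed=11)
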