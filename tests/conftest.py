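import numpy as np
import pytest

import gabarect.biophysics as bp
from gabarect.cable import SimConfig, single_compartment_grid
from gabarect.morphology import generate_synthetic_ca1
from gabarect.protocols import branch_model, fullcell_model


@pytest.fixture(scope="session")
def passive():
    return bp.PassiveConstants()


@pytest.fixture(scope="session")
def leak_channels(passive):
    return [bp.ChannelSpec("leak", bp.DensityRule(1.0 / passive.r_m), -70.0)]


@pytest.fixture(scope="session")
def patch_grid(leak_channels, passive):
    """Isopotential 1000-um^2 passive patch (R = 6 GOhm, tau = 60 ms)."""
    return single_compartment_grid(1000.0, leak_channels, passive)


@pytest.fixture(scope="session")
def branch_grid():
    return branch_model()


@pytest.fixture(scope="session")
def ca1_morph():
    return generate_synthetic_ca1(seed=1)


@pytest.fixture(scope="session")
def fullcell_grid():
    return fullcell_model(seed=0)


@pytest.fixture(scope="session")
def quick_cfg():
    """Short settle for fast unit-level simulations."""
    return SimConfig(dt=0.025, t_stop=150.0, settle=300.0)
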