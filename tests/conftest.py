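import numpy as np
import pytest

from rotorchain import PhysicalParams
from rotorchain.hydrodynamics import FluidContext


@pytest.fixture(scope="session")
def ctx() -> FluidContext:
    """Reference fluid: 6 mPa s water-glycerol, 1.74 um silica beads."""
    return FluidContext(mu=6e-3, a=1.74e-6)


@pytest.fixture(scope="session")
def pair_params() -> PhysicalParams:
    """Reference two-rotor configuration at the lowest experimental height."""
    return PhysicalParams(N=2, h=4.2e-6)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160913)
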