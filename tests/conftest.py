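import numpy as np
import pytest

from pbreactor import (FluidProperties, PingPongParams, ReactorSpec,
                       solve_axial_dispersion)
from pbreactor.model import OperatingPoint, Scenario


@pytest.fixture(scope="session")
def spec():
    return ReactorSpec()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def kinetics_params():
    return PingPongParams()


@pytest.fixture(scope="session")
def scenario():
    return Scenario()


@pytest.fixture(scope="session")
def base_op():
    """The reference operating point: 5 mL/min, 150/150/300 mM feed."""
    return OperatingPoint.equimolar(5.0, 300.0)


@pytest.fixture(scope="session")
def base_cfg(scenario, base_op):
    return scenario.model_config(base_op)


@pytest.fixture(scope="session")
def base_profile(base_cfg):
    """Base-case solve, shared across tests (read-only)."""
    return solve_axial_dispersion(base_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201026)
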