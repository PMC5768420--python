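import numpy as np
import pytest

from neurite_switch import (
    SubstrateCondition,
    SwitchParameters,
    reference_parameters,
)


@pytest.fixture(scope="session")
def ref_params() -> SwitchParameters:
    """The shipped reference calibration."""
    return reference_parameters()


@pytest.fixture(scope="session")
def soft() -> SubstrateCondition:
    return SubstrateCondition(0.1, "0.1 kPa")


@pytest.fixture(scope="session")
def stiff() -> SubstrateCondition:
    return SubstrateCondition(20.0, "20 kPa")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
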