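import math

import pytest

from dipsway import (
    AnthropometricParameters,
    JointState,
    NoiseConfig,
    SimulationConfig,
)


@pytest.fixture(scope="session")
def anthro() -> AnthropometricParameters:
    return AnthropometricParameters()


@pytest.fixture()
def reference() -> JointState:
    return JointState.reference()


@pytest.fixture(scope="session")
def noiseless_offset_config() -> SimulationConfig:
    """Short noiseless run from a 0.5 deg ankle offset, default ankle strategy."""
    return SimulationConfig(
        seed=0,
        duration=5.0,
        transient_discard=1.0,
        noise=NoiseConfig(target_std=0.0),
        initial_state=JointState(q1=math.pi / 2 + math.radians(0.5)),
    )
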