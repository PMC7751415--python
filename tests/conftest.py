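import numpy as np
import pytest

from magsteer.magnetics import CoilSpec, ParticleSpec
from magsteer.scenarios import build_scenario, ci_setup, default_setup


@pytest.fixture
def particle() -> ParticleSpec:
    """400 nm magnetite particle at room temperature."""
    return ParticleSpec(core_diameter=400e-9, saturation_magnetization=4.78e5,
                        temperature=300.0)


@pytest.fixture
def coil() -> CoilSpec:
    return CoilSpec(center=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                    radius=0.05, turns=100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def ci_scenario():
    """Scaled steering scenario shared across optimizer tests."""
    return build_scenario(ci_setup())


@pytest.fixture(scope="session")
def nominal_scenario():
    """Reference 31x31 steering scenario."""
    return build_scenario(default_setup())
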