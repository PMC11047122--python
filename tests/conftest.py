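import numpy as np
import pytest

from crconset.simulate import SimulationSpec


@pytest.fixture(scope="session")
def spec() -> SimulationSpec:
    """Default study-condition simulation spec with a fixed seed."""
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
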