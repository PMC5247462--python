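import numpy as np
import pytest

from bodyn.config import RunConfig
from bodyn.model import BONetwork


@pytest.fixture(scope="session")
def cfg50() -> RunConfig:
    """The half-scale configuration used for the simulation experiments."""
    return RunConfig(grid=50)


@pytest.fixture(scope="session")
def net50(cfg50) -> BONetwork:
    """One shared network instance (kernel rendering and JIT are costly)."""
    return BONetwork(cfg50)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
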