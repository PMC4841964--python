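import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20160423)


@pytest.fixture
def cfg():
    from cnvdrop.simulate import SimulationConfig

    return SimulationConfig()


@pytest.fixture(scope="session")
def table1():
    from cnvdrop.table1 import load_table1

    return load_table1()
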