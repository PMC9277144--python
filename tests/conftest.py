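import pytest
from hypothesis import HealthCheck, settings

from srbkin import (
    acetate_reactor_config,
    acetate_reactor_scenario,
    lactate_reactor_config,
    lactate_reactor_scenario,
)

settings.register_profile(
    "srbkin",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("srbkin")


@pytest.fixture(scope="session")
def lactate_config():
    return lactate_reactor_config()


@pytest.fixture(scope="session")
def acetate_config():
    return acetate_reactor_config()


@pytest.fixture(scope="session")
def noiseless_lactate_scenario():
    return lactate_reactor_scenario(seed=0, cv=0.0)


@pytest.fixture(scope="session")
def noiseless_acetate_scenario():
    return acetate_reactor_scenario(seed=0, cv=0.0)
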