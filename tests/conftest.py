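import pytest
from hypothesis import settings

from abpsim import EngineConfig, default_template, make_synthetic_scenario

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def template():
    """The packaged default beat (250 Hz, 47 bpm synthetic morphology)."""
    return default_template()


@pytest.fixture()
def steady_scenario():
    """Constant 70 bpm, 120/80 mmHg for 10 s."""
    return make_synthetic_scenario("steady", duration=10.0)


@pytest.fixture()
def config():
    return EngineConfig()
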