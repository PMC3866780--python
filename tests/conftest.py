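import pytest
from hypothesis import HealthCheck, settings

from cyclopk.config import default_config

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_config():
    return default_config()


@pytest.fixture(scope="session")
def study_compounds(study_config):
    """The three bundled compounds, keyed by name."""
    return {c.name: c.to_parameters() for c in study_config.compounds}
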