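import pytest

from nafcflow.pipeline import run_pipeline
from nafcflow.synthetic import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def bundle():
    """The default seeded fixture used across recovery tests."""
    return generate_fixture(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def result(bundle):
    """Full pipeline output on the default fixture."""
    return run_pipeline(bundle)
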