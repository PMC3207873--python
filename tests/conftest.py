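import pytest

from afchoice.patient_model import generate_fixtures
from helpers import build_profile


@pytest.fixture
def make_profile():
    """Factory for valid profiles with all flags defaulting to false."""
    return build_profile


@pytest.fixture(scope="session")
def fixture_profiles():
    """A reproducible batch of synthetic profiles shared across tests."""
    return generate_fixtures(500, seed=20110)
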