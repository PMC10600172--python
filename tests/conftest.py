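import pytest

from damscore.pipeline import session_features
from damscore.synthetic import default_scenario, simulate_session


@pytest.fixture(scope="session")
def session():
    """One standard 60 s simulated recording shared across test modules."""
    return simulate_session(default_scenario(7))


@pytest.fixture(scope="session")
def joined(session):
    return session.joined()


@pytest.fixture(scope="session")
def fm_and_labels(session):
    return session_features(session)
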