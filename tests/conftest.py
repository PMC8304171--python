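import pytest

from courtentropy import CourtGeometry, SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def geom():
    return CourtGeometry()


@pytest.fixture(scope="session")
def small_corpus():
    """Six synthetic matches, fixed seed; shared across read-only tests."""
    return generate_corpus(SyntheticConfig(n_matches=6, seed=123)).matches
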