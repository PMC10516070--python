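import pytest

from nearcoding.synthdata import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted synthetic fixture (genome edited, truth verified)."""
    return make_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def fixture_transcripts(default_fixture):
    return default_fixture[1]
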