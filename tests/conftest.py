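import pytest
from hypothesis import settings

from otoshell import normalize, summarize_set, toadfish_fixture

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toadfish():
    return toadfish_fixture()


@pytest.fixture(scope="session")
def normalized_summaries(toadfish):
    return normalize(summarize_set(toadfish), reference="auto")
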