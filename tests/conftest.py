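import pytest
from hypothesis import HealthCheck, settings

from casemeta import apply_analysis_set
from casemeta import mpsii

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def corpus():
    """The packaged 56-case MPS-II corpus."""
    return mpsii.load_corpus()


@pytest.fixture(scope="session")
def primary(corpus):
    """The 44-case primary analysis set."""
    return apply_analysis_set(corpus, mpsii.PRIMARY_SET)


@pytest.fixture(scope="session")
def outcomes(corpus):
    return corpus.outcomes
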