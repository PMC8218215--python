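import pytest
from hypothesis import HealthCheck, settings

from nicotweet import Lemmatizer, load_lexicon, load_stopwords

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stopwords():
    return load_stopwords()


@pytest.fixture(scope="session")
def lemmatizer():
    return Lemmatizer()


@pytest.fixture(scope="session")
def lexicon(lemmatizer):
    return load_lexicon(lemmatizer=lemmatizer)
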