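import pytest

from bdforum.cohort import default_patterns
from bdforum.corpus import Post
from bdforum.lexicon import default_lexicon
from bdforum.taxonomy import fixture_taxonomy

BASE_TS = 1500000000  # 2017-07-14 UTC, safely past site inception


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


@pytest.fixture(scope="session")
def taxonomy():
    return fixture_taxonomy()


def make_post(pid="p1", author="u1", subreddit="askreddit", ts=BASE_TS, body=""):
    return Post(id=pid, author=author, subreddit=subreddit, created_utc=ts, body=body)


@pytest.fixture
def post_factory():
    return make_post
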