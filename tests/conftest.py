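import pytest

from tabsearch.fixtures import gen_random_entry
from tabsearch.search import SearchParams


@pytest.fixture
def small_pair():
    """A random 4-SSE / 5-SSE entry pair with mixed types."""
    A = gen_random_entry(4, seed=11, entry_id="A4")
    B = gen_random_entry(5, seed=22, entry_id="B5")
    return A, B


@pytest.fixture
def fast_params():
    return SearchParams(restarts=16, seed=1)
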