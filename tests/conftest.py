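import pytest

from loxscape import make_genome
from loxscape.caller import FlankIndex
from loxscape.fixtures import six_site_genome


@pytest.fixture(scope="session")
def toy():
    return make_genome("toy", 0)


@pytest.fixture(scope="session")
def ring():
    return make_genome("ring", 0)


@pytest.fixture(scope="session")
def mini():
    return make_genome("mini", 0)


@pytest.fixture(scope="session")
def six_site():
    return six_site_genome(0)


@pytest.fixture(scope="session")
def toy_index(toy):
    return FlankIndex(toy, min_flank=20)
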