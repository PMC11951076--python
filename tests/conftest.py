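import pytest

import pufatyper as pt
from pufatyper.synthetic_data import default_reference_library


@pytest.fixture(scope="session")
def panel():
    return pt.load_panel()


@pytest.fixture(scope="session")
def registry():
    return pt.load_registry()


@pytest.fixture(scope="session")
def fixture_matrix():
    return pt.build_fixture_matrix()


@pytest.fixture(scope="session")
def archetypes(panel, registry):
    return default_reference_library(panel, registry)
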