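import numpy as np
import pytest

from ophiopsin.references import (
    DiagnosticScheme,
    default_outgroup,
    default_panel,
    get_anchor,
)
from ophiopsin.seqcore import ScoringScheme


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def anchor(panel):
    return get_anchor(panel)


@pytest.fixture(scope="session")
def scheme():
    return DiagnosticScheme()


@pytest.fixture(scope="session")
def sc():
    return ScoringScheme()


@pytest.fixture(scope="session")
def outgroup():
    return default_outgroup()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
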