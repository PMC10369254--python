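import pytest

from stranddecoder import fixtures
from stranddecoder.model import GeneticDecoder


@pytest.fixture(scope="session")
def cyp_decoder():
    return GeneticDecoder.from_fixture("CYP2C19")


@pytest.fixture(scope="session")
def cyp_fit(cyp_decoder):
    return cyp_decoder.fit()


@pytest.fixture(scope="session")
def dpyd_decoder():
    return GeneticDecoder.from_fixture("DPYD")


@pytest.fixture(scope="session")
def dpyd_fit(dpyd_decoder):
    return dpyd_decoder.fit()


@pytest.fixture(scope="session")
def cyp_panel():
    return fixtures.cyp2c19_panel()


@pytest.fixture(scope="session")
def synthetic_scoring():
    return fixtures.synthetic_scoring_model()
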