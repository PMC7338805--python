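import numpy as np
import pytest

from introscreen.locus import build_psmc3_fixture
from introscreen.pedigree import family_pedigree
from introscreen.simulate import SimScenario
from introscreen.splice import default_acceptor_model, default_donor_model


@pytest.fixture(scope="session")
def fixture():
    return build_psmc3_fixture()


@pytest.fixture(scope="session")
def donor_model():
    return default_donor_model()


@pytest.fixture(scope="session")
def acceptor_model():
    return default_acceptor_model()


@pytest.fixture()
def ped():
    return family_pedigree()


@pytest.fixture()
def scenario():
    return SimScenario(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
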