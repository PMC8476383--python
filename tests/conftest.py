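import numpy as np
import pytest

from myelinmap.growth import reference_growth_params
from myelinmap.mp2rage import build_lookup
from myelinmap.protocol import STUDY_PROTOCOL


@pytest.fixture(scope="session")
def protocol():
    return STUDY_PROTOCOL


@pytest.fixture(scope="session")
def lookup(protocol):
    return build_lookup(protocol)


@pytest.fixture(scope="session")
def reference_params():
    return reference_growth_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
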