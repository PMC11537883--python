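import numpy as np
import pytest

from rp17sv import DEFAULT_LOCUS, fixtures, load_catalogue
from rp17sv.annotation import load_locus_model


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def catalogue_svs(catalogue):
    return [e.sv for e in catalogue]


@pytest.fixture(scope="session")
def sv_by_id(catalogue_svs):
    return {sv.id: sv for sv in catalogue_svs}


@pytest.fixture(scope="session")
def locus():
    return DEFAULT_LOCUS


@pytest.fixture(scope="session")
def locus_model():
    return load_locus_model()


@pytest.fixture(scope="session")
def toy():
    return fixtures.toy_locus(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
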