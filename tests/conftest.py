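import numpy as np
import pytest

from viroscreen.search import ScoringScheme
from viroscreen.synthdata import make_toy_vpd, template_bundle
from viroscreen.vpd import VpdDatabase

AA20 = list("ARNDCQEGHILKMFPSTWYV")


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def templates():
    return template_bundle()


@pytest.fixture(scope="session")
def toy_vpd():
    return VpdDatabase(entries=make_toy_vpd())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, n):
    return "".join(rng.choice(AA20, size=n))


def random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
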