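import numpy as np
import pytest

from gyrits.models import SubstitutionModel
from gyrits.synthetic_data import ITSTemplate, make_reference_its


@pytest.fixture(scope="session")
def jc():
    return SubstitutionModel.jc()


@pytest.fixture(scope="session")
def tvm_gamma():
    return SubstitutionModel.tvm(1.3, 2.8, 0.7, 1.1, 0.9,
                                 (0.28, 0.18, 0.22, 0.32), gamma_shape=0.8)


@pytest.fixture(scope="session")
def sym_gamma():
    return SubstitutionModel.sym((1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
                                 gamma_shape=0.8)


@pytest.fixture(scope="session")
def clean_record():
    """A clean synthetic ITS record mirroring a mid-length submission."""
    tpl = ITSTemplate(its1_len=345, its2_len=332, seed=7)
    seq, truth = make_reference_its(tpl)
    return tpl, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240923)
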