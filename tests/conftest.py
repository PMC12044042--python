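import numpy as np
import pytest

from amyenc.data import Parcellation
from amyenc.hrf import canonical_hrf
from amyenc.synthetic import make_parcellation, make_toy_networks


@pytest.fixture(scope="session")
def hrf_tr1():
    return canonical_hrf(dt=1.0)


@pytest.fixture(scope="session")
def small_parcellation() -> Parcellation:
    return make_parcellation(
        {"LB": 10, "CM": 5, "SF": 5, "AStr": 4, "VC": 30, "IT": 12}, seed=1
    )


@pytest.fixture(scope="session")
def toy_networks():
    return make_toy_networks(d_z=6, F=12, H=16, W=16, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
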