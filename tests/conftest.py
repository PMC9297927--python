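import numpy as np
import pytest

from csdsim import BroodModel, CrossScheme, CsdParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def heterotoma():
    return CrossScheme.preset("heterotoma")


@pytest.fixture
def clavipes():
    return CrossScheme.preset("clavipes")


@pytest.fixture
def k1():
    return CsdParams(n_loci=1)


@pytest.fixture
def small_brood_model():
    return BroodModel.parametric(mean=20.0, dispersion=5.0, beta_a=6.5, beta_b=3.5)
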