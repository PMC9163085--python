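import numpy as np
import pytest

from sfcoupling import (
    build_predictors,
    gen_connectome,
    gen_geometry,
)


@pytest.fixture(scope="session")
def geometry20():
    return gen_geometry(20, seed=7)


@pytest.fixture(scope="session")
def sc20(geometry20):
    return gen_connectome(geometry20, density=0.35, length_scale=40.0, seed=7)


@pytest.fixture(scope="session")
def predictors20(geometry20, sc20):
    return build_predictors(geometry20, sc20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
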