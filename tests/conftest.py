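import numpy as np
import pytest

from sacsim import ModelParameters, default_parameters
from sacsim.sc import SCGeometry


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def geometry(params) -> SCGeometry:
    return SCGeometry.from_params(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
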