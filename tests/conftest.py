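import numpy as np
import pytest

from piliagg import PairPotentialParams, build_cell_template


@pytest.fixture(scope="session")
def params():
    return PairPotentialParams()


@pytest.fixture(scope="session")
def params_nonadhesive():
    return PairPotentialParams(A=0.0)


@pytest.fixture(scope="session")
def localized_template(params):
    return build_cell_template("localized", params, 19)


@pytest.fixture(scope="session")
def dispersed_template(params):
    return build_cell_template("dispersed", params, 19)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
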