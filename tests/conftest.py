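import numpy as np
import pytest

from sdspike import params as P
from sdspike.currents import make_current_model
from sdspike.cable_response import ResponseKernel


@pytest.fixture(scope="session")
def standard():
    return P.load_parameter_set("standard")


@pytest.fixture(scope="session")
def fitted():
    return P.load_parameter_set("fitted")


@pytest.fixture(scope="session")
def kernel_D(standard):
    return ResponseKernel.from_parameter_set(standard)


@pytest.fixture(scope="session")
def kernel_A(standard):
    return ResponseKernel.from_parameter_set(
        standard.with_current(make_current_model("A", I0=6.6)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
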