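import numpy as np
import pytest

from perisacc.eye_events import bin_left_edges
from perisacc.kernels import default_kernels


@pytest.fixture(scope="session")
def kernels():
    return default_kernels()


@pytest.fixture()
def bins():
    return bin_left_edges()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
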