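import numpy as np
import pytest

from odcell.reference import load_reference_table


@pytest.fixture(scope="session")
def table():
    return load_reference_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
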