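import numpy as np
import pytest

from vitalink.fixtures import load_fixture


@pytest.fixture(scope="session")
def hr_table():
    return load_fixture("hr")


@pytest.fixture(scope="session")
def spo2_table():
    return load_fixture("spo2")


@pytest.fixture(scope="session")
def temp_table():
    return load_fixture("temp")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
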