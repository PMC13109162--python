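import numpy as np
import pandas as pd
import pytest

from ewsval import generate_worked_fixture, load_band_table


@pytest.fixture(scope="session")
def news():
    return load_band_table("news")


@pytest.fixture(scope="session")
def gews():
    return load_band_table("gews")


@pytest.fixture(scope="session")
def worked_fixture():
    """(patients, observations, events, expected-labels) hand-built dataset."""
    return generate_worked_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
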