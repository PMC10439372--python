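import logging

import numpy as np
import pytest
from hypothesis import settings

import cuffmc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

logging.getLogger("cuffmc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def human():
    return cuffmc.load_default("human")


@pytest.fixture(scope="session")
def chimp():
    return cuffmc.load_default("chimpanzee")


@pytest.fixture(scope="session")
def human_mid_model(human):
    return cuffmc.GlenohumeralModel(human, "mid_support")


@pytest.fixture(scope="session")
def chimp_mid_model(chimp):
    return cuffmc.GlenohumeralModel(chimp, "mid_support")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
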