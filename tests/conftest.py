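import numpy as np
import pytest
from hypothesis import settings

import symptomnet as sn

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def junior_model():
    return sn.study_preset("junior")


@pytest.fixture(scope="session")
def senior_model():
    return sn.study_preset("senior")


@pytest.fixture(scope="session")
def junior_data(junior_model):
    """One moderate junior sample reused across read-only tests."""
    return sn.sample(junior_model, 2000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_weights(rng, p, density=0.5):
    """Random sparse symmetric zero-diagonal weight matrix for property tests."""
    W = rng.uniform(-0.4, 0.4, size=(p, p))
    W = np.triu(W, 1) * (rng.random((p, p)) < density)
    return W + W.T
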