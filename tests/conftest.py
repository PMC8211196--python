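import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ea3 import RankingVector, paracetamol_constants, paracetamol_surveys

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1868)


@pytest.fixture
def equal3():
    return RankingVector.equal(3)


@pytest.fixture
def surveys():
    return paracetamol_surveys()


@pytest.fixture
def constants():
    return paracetamol_constants()


def random_inputs(rng, k=None):
    """One random admissible (appraisals, ranking, beta) triple."""
    if k is None:
        k = int(rng.integers(2, 7))
    a = rng.uniform(0.0, 1.0, size=k)
    r = RankingVector.normalised(rng.uniform(0.05, 1.0, size=k))
    beta = float(rng.uniform(0.05, 20.0))
    return a, r, beta
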