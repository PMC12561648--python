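import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from keyslice.pipeline import oracle_from_cohort, volume_embeddings
from keyslice.synthetic import make_fixture_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Noiseless 6-study phantom cohort with exact ground truth."""
    return make_fixture_cohort(6, seed=7)


@pytest.fixture(scope="session")
def oracle(cohort):
    return oracle_from_cohort(cohort)


@pytest.fixture(scope="session")
def oracle_embeddings(oracle, cohort):
    """Slice embeddings of every study under the oracle, computed once."""
    return volume_embeddings(oracle, cohort, None)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
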