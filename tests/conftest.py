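import numpy as np
import pytest
from hypothesis import settings

from qsofa_hbp.synthetic_cohort import default_cohort_spec, generate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def study_cohort():
    """One packaged-size (n=794) synthetic cohort, shared across tests."""
    return generate_cohort(default_cohort_spec(seed=3))


@pytest.fixture(scope="session")
def big_cohort():
    """A large (n=10,000) cohort for distribution-recovery checks."""
    return generate_cohort(default_cohort_spec(n=10_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
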