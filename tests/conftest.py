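import numpy as np
import pytest
from hypothesis import settings

from ibaskit import cohort

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_cohort():
    """One deterministic cohort at the published size (150 per group)."""
    return cohort.generate(cohort.default_profile(), seed=11)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for moment checks (5000 per group)."""
    return cohort.generate(cohort.default_profile(n_per_group=5000), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
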