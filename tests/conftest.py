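import numpy as np
import pytest
from hypothesis import settings

import snpmediate as sm

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_small():
    """Pathway-1 cohort at modest size for fit/bootstrap tests."""
    params = sm.default_params(1, n_subjects=400, seed=20240101)
    cohort, truth = sm.simulate_cohort(params)
    return cohort, truth


@pytest.fixture(scope="session")
def spec1():
    return sm.PathwaySpec("geno_snp1", "vitd", "ua")


@pytest.fixture(scope="session")
def fitted_small(cohort_small, spec1):
    cohort, _ = cohort_small
    return sm.fit_pathway(cohort, spec1)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
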