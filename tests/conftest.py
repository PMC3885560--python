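import numpy as np
import pytest
from hypothesis import settings

from ogttmet.synthetic import CohortConfig, generate_cohort

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort: full study design, 40 metabolites, fast to generate."""
    return CohortConfig(n_metabolites=40, n_planted=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
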