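import numpy as np
import pytest

from alcogla.pipeline import build_analysis_table
from alcogla.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-configuration cohort shared across unit tests."""
    return generate_cohort(CohortConfig(n_participants=6000, seed=123))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_analysis_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
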