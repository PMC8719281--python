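import numpy as np
import pytest

from braindex import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """200 subjects/group with the default planted deficit."""
    return simulate_cohort(CohortConfig(n_per_group=200, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
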