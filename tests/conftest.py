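import numpy as np
import pytest

from cogscreen.cohort import load_printed_fixture_frame
from cogscreen.synthetic import CohortSimConfig, generate_cohort


@pytest.fixture(scope="session")
def printed():
    """The packaged printed per-patient score table (86 rows)."""
    return load_printed_fixture_frame()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient synthetic cohort shared across fast tests."""
    records, truth = generate_cohort(CohortSimConfig(n=30, seed=7))
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
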