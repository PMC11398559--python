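import logging

import pytest

from pshtraj.scoring import DEFAULT_RUBRICS, score_cohort
from pshtraj.simulate import CohortConfig, generate_cohort

logging.getLogger("pshtraj").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rubrics():
    return DEFAULT_RUBRICS


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient default-condition cohort shared across tests."""
    return generate_cohort(CohortConfig(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def scored_small(small_cohort):
    daily, matrix, excluded = score_cohort(small_cohort.vitals, small_cohort.flags)
    assert not excluded
    return daily, matrix
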