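import warnings

import numpy as np
import pytest

from svdlatent.cohort import CohortConfig, generate_cohort, prepare_markers


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration cohort at the reference sample size."""
    return generate_cohort(CohortConfig(n_participants=892, seed=5))


@pytest.fixture(scope="session")
def prepared_cohort(default_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepared, record = prepare_markers(default_cohort)
    return prepared


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for convergence checks."""
    return generate_cohort(CohortConfig(n_participants=100_000, seed=17))
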