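import numpy as np
import pytest

import robscore as rs


@pytest.fixture(scope="session")
def criteria():
    return rs.ScoringCriteria.default()


@pytest.fixture(scope="session")
def cohort_ledger():
    """The bundled reconstructed validation-cohort event ledger."""
    return rs.reference_cohort()


@pytest.fixture(scope="session")
def scored_cohort(cohort_ledger):
    _, scored, _ = rs.build_valid_cohort(cohort_ledger)
    return scored


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
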