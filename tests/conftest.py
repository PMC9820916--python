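import numpy as np
import pytest

from airwaymorph.synthetic import (CohortSpec, generate_cohort,
                                   template_landmarks, template_measures)


@pytest.fixture(scope="session")
def template():
    return template_landmarks()


@pytest.fixture(scope="session")
def template_vals():
    return template_measures()


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects with grids, shared across tests (read-only)."""
    return generate_cohort(CohortSpec(n=12, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
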