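import numpy as np
import pytest

from mpmri import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_aif():
    """Gamma-variate bolus on the default 1.5 s grid."""
    return simulate.make_aif()


@pytest.fixture(scope="session")
def cohort_table():
    """A pinned 14 + 14 synthetic cohort."""
    table, truth = simulate.make_cohort(simulate.CohortDesign(seed=7))
    return table, truth
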