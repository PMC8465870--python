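import numpy as np
import pytest

from swaysom import cohort, som


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_grid():
    return som.SOMGrid(4, 4)


@pytest.fixture
def rect_2x2():
    return som.SOMGrid(2, 2, topology="rectangular")


@pytest.fixture
def tiny_cohort_config():
    """Small, fast cohort: 4 subjects, 10 s conditions."""
    return cohort.CohortConfig(n_subjects=4, duration=10.0, rng_seed=7)


@pytest.fixture
def profile():
    return cohort.SubjectProfile("01", height=173.6, com_height_L=92.0)
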