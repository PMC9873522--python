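import numpy as np
import pytest

from nvcoupling.volumes import Grid, MaskMap, ScalarMap


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def grid5():
    return Grid.isotropic((5, 5, 5), 3.0)


@pytest.fixture
def full_mask5(grid5):
    return MaskMap(grid5, np.ones(grid5.shape, bool))


def make_map(grid, values):
    return ScalarMap(grid, np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort (8 patients, 8 controls)."""
    from nvcoupling.simulate import CohortParams, generate_cohort

    return generate_cohort(CohortParams(n_patients=8, n_controls=8), seed=11)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    from nvcoupling.study import NVCStudy

    study = NVCStudy.from_cohort(small_cohort)
    return study, study.fit()
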