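import numpy as np
import pytest

from cxropt import GenParams, gen_clinical_cohort, gen_enriched_cohort


@pytest.fixture(scope="session")
def default_params():
    return GenParams()


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down study for fast end-to-end tests."""
    return GenParams(
        n_clinical_by_subgroup={"inpatient": 2_000, "outpatient": 1_000},
        sample_reading_per_subgroup=100,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_params):
    return (
        gen_enriched_cohort(small_params, seed=7),
        gen_clinical_cohort(small_params, seed=7),
    )


@pytest.fixture(scope="session")
def paper_scale_cohorts(default_params):
    return (
        gen_enriched_cohort(default_params, seed=11),
        gen_clinical_cohort(default_params, seed=11),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
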