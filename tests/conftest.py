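import pytest

import methpanel as mp


@pytest.fixture(scope="session")
def small_config():
    """Fast desk-scale cohort used by most integration-level tests."""
    return mp.CohortConfig(
        n_cancer=60,
        n_normal=40,
        n_sites=300,
        n_informative=12,
        n_bad_sites=6,
        n_bad_patients=2,
        n_unmapped=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return mp.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    matrix = mp.drop_unmapped_sites(small_cohort)
    matrix, _ = mp.filter_missing(matrix)
    matrix = mp.impute_site_mean(matrix)
    return mp.split_dataset(matrix, seed=5)
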