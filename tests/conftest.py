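import numpy as np
import pytest

from mwoa.feature_selection import OneNearestNeighborClassifier
from mwoa.synthetic import CohortProfile, generate, planted_subset_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """An imputable hypertensive cohort with missingness and imbalance."""
    return generate(
        CohortProfile(name="hypertensive", n_samples=600, missing_rate=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """A complete (no-missing) normotensive cohort."""
    return generate(CohortProfile(name="normotensive", n_samples=600, seed=12))


@pytest.fixture(scope="session")
def planted():
    """8-feature dataset whose labels depend only on features {0, 1, 2}."""
    dataset, truth = planted_subset_dataset(8, {0, 1, 2}, 300, noise_sd=0.3, seed=5)
    return dataset, truth


@pytest.fixture(scope="session")
def surrogate():
    """Fast deterministic classifier factory for wrapper tests."""
    return OneNearestNeighborClassifier


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
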