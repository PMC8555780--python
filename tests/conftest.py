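import numpy as np
import pytest

from ddcat.fitness import FitnessConfig
from ddcat.patterns import standard_categorization
from ddcat.synthetic import fixture_small


@pytest.fixture(scope="session")
def fix():
    """The small planted-truth fixture shared by all suites."""
    return fixture_small(seed=0)


@pytest.fixture(scope="session")
def dataset(fix):
    return fix.dataset_bundle()


@pytest.fixture(scope="session")
def standard_cat():
    cat = standard_categorization()
    cat.build_assignment_table()
    return cat


@pytest.fixture(scope="session")
def fast_fitness_config():
    """Scaled-down fitness settings used for GA-level tests."""
    return FitnessConfig(k_range_radius=1, nmf_restarts=2, nmf_max_iter=400,
                         nmf_tol=1e-5, n_folds=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
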