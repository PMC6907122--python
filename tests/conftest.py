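import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from comorbinet import ingest, synthetic


@pytest.fixture(scope="session")
def small_cohort_config():
    return synthetic.make_cohort_config(
        500, 20, 4, mean_prevalence=0.05, within_module_boost=4.0, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return synthetic.generate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return ingest.build_profiles(small_cohort)


@pytest.fixture(scope="session")
def boosted_cohort_config():
    """Medium cohort with strong planted modules, reused by several suites."""
    return synthetic.make_cohort_config(
        20_000, 40, 4, mean_prevalence=0.02, within_module_boost=8.0, seed=1
    )


@pytest.fixture(scope="session")
def boosted_profiles(boosted_cohort_config):
    return ingest.build_profiles(synthetic.generate_cohort(boosted_cohort_config))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_contingency(rng, n_max=200):
    """A random valid (c_ij, p_i, p_j, n) with non-degenerate prevalences."""
    n = int(rng.integers(10, n_max))
    p_i = int(rng.integers(1, n))
    p_j = int(rng.integers(1, n))
    lo = max(0, p_i + p_j - n)
    hi = min(p_i, p_j)
    c = int(rng.integers(lo, hi + 1))
    return c, p_i, p_j, n
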