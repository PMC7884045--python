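import numpy as np
import pytest

import twinewas as tw


@pytest.fixture(scope="session")
def madt_cohort():
    """Discovery-profile cohort: 200 MZ pairs."""
    return tw.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """50 MZ pairs, for cheap model fits."""
    return tw.generate_cohort(tw.CohortConfig(n_pairs=50), seed=11)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Half MZ / half DZ pairs."""
    return tw.generate_cohort(tw.CohortConfig(n_pairs=100, zygosity_mix=0.5), seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
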