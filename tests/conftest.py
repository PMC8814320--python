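import numpy as np
import pandas as pd
import pytest

from deprivmr import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Family cohort of ~900 individuals with non-null deprivation and
    cortisol effects, shared across tests that only read it."""
    cfg = SimConfig(n_neighborhoods=15, households_per_neighborhood=20, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def unrelated_cohort():
    """~1,000 unrelated singleton-household individuals."""
    cfg = SimConfig(n_neighborhoods=25, households_per_neighborhood=40,
                    mean_household_size=1.0, sibling_fraction=0.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
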