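import numpy as np
import pytest
from hypothesis import settings

from aucreshape import BoostSchedule, SyntheticSpec, generate_splits

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_schedule():
    """Uniform boost 0.2 at the four high-specificity levels."""
    return BoostSchedule.uniform(0.2, [0.90, 0.92, 0.95, 0.98])


@pytest.fixture(scope="session")
def small_splits():
    """Small train/validation/test tables for fast harness tests."""
    spec = SyntheticSpec(n_pos=600, n_neg=80, dims=4, seed=7)
    return generate_splits(spec)
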