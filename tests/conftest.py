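import numpy as np
import pytest

from newsy import CFAModel, ExposureEffectConfig, generate_factor_items
from newsy.registry import load_builtin_model
from newsy.simulate import default_profiles, generate_full_cohort


@pytest.fixture(scope="session")
def australia_spec():
    return load_builtin_model("final_australia")


@pytest.fixture(scope="session")
def australia_items_20k(australia_spec):
    """Large continuous item sample from the final Australian model."""
    return generate_factor_items(australia_spec, 20_000, seed=20240)


@pytest.fixture(scope="session")
def australia_fit_20k(australia_spec, australia_items_20k):
    return CFAModel.from_data(australia_items_20k, australia_spec).fit()


@pytest.fixture(scope="session")
def full_cohort():
    """All 15 countries, published exposure effects, fixed seed."""
    return generate_full_cohort(
        default_profiles(), ExposureEffectConfig.published(), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
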