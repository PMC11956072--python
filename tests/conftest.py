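import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dqqkit import default_scenario, food_group_codes, generate_population
from dqqkit.taxonomy import FoodGroupVector

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def codes() -> tuple[str, ...]:
    return food_group_codes()


@pytest.fixture(scope="session")
def empty_vector(codes) -> FoodGroupVector:
    return FoodGroupVector({c: False for c in codes})


@pytest.fixture(scope="session")
def full_vector(codes) -> FoodGroupVector:
    return FoodGroupVector({c: True for c in codes})


@pytest.fixture(scope="session")
def default_dataset() -> pd.DataFrame:
    """One generated default-scenario dataset, shared across tests."""
    return generate_population(default_scenario(seed=20240101)).frame


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(8675309)
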