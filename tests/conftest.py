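import numpy as np
import pytest

from speakvar.phone_features import (
    CostScheme,
    FeatureTable,
    default_cost_scheme,
    default_feature_table,
)
from speakvar.affix_coding import default_target_language


@pytest.fixture(scope="session")
def table() -> FeatureTable:
    return default_feature_table()


@pytest.fixture(scope="session")
def scheme(table) -> CostScheme:
    return default_cost_scheme(table)


@pytest.fixture(scope="session")
def language(table):
    return default_target_language(table)


@pytest.fixture(scope="session")
def mini_table() -> FeatureTable:
    """A 4-phoneme inventory (2 vowels, 2 consonants) for exhaustive checks."""
    return FeatureTable(
        {"a": (0.0, 0.5), "ɔ": (0.5, 0.0)},
        {"b": (0, 1, 1, 1, 0, 0, 0, 0), "m": (0, 1, 1, 1, 1, 0, 0, 0)},
    )


@pytest.fixture(scope="session")
def mini_scheme(mini_table) -> CostScheme:
    return CostScheme.from_table(mini_table)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
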