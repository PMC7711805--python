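import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from udseeg import FeatureMatrix, default_profiles, generate_feature_table


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def feature_table_800(profiles) -> FeatureMatrix:
    """The study-scale labeled feature table (800 epochs per class)."""
    return generate_feature_table(profiles, n_per_class=800, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
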