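import numpy as np
import pytest

from pectiml import SyntheticConfig, generate
from pectiml.pipeline import Dataset, build_feature_table


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared across the session."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """(Dataset, FeatureTable, training X, training y) for the default data."""
    d = Dataset.from_synthetic(default_dataset)
    table = build_feature_table(d)
    X, y = d.training_frame(table)
    return d, table, X, np.asarray(y)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
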