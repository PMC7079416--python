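import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miress.features import extract_features
from miress.synthetic import generate_dataset, strong_signal_spec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """12+12 short synthetic hairpins, strong class signal."""
    spec = strong_signal_spec(
        seed=11,
        n_pos=12,
        n_neg=12,
        stem_len_range=(20, 24),
        loop_len_range=(4, 8),
        mature_len_range=(18, 20),
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Feature matrix and labels for the small dataset (simple backend)."""
    vectors = [extract_features(r) for r in small_dataset]
    X = np.array([v.values for v in vectors])
    y = np.array([v.label for v in vectors])
    return X, y, vectors
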