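import numpy as np
import pytest

from smtl import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240807)


@pytest.fixture
def small_table(rng):
    """12 samples, 6 features in two modalities, balanced classes."""
    X = rng.standard_normal((12, 6))
    labels = np.array([1] * 6 + [-1] * 6)
    X[labels == 1, 0] += 2.0  # one clearly informative feature
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(12)],
        X=X,
        labels=labels,
        modality_of={0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"},
        feature_names=[f"f{j}" for j in range(6)],
    )
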