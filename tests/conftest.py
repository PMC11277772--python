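import numpy as np
import pytest

from pulmotex.synthetic import generate_feature_table, generate_phantom


@pytest.fixture(scope="session")
def planted_easy():
    """N=200, M=12, 2 informative features at effect 3."""
    return generate_feature_table(200, 12, 2, 3.0, seed=11)


@pytest.fixture(scope="session")
def label_equals_feature_table():
    """Feature 0 is the label itself plus 9 noise columns: perfectly
    separable, a sanity anchor for classifiers and importances."""
    from pulmotex.types import FeatureTable

    rng = np.random.default_rng(5)
    labels = np.tile([1, 2, 3], 60)
    X = rng.normal(size=(180, 10))
    X[:, 0] = labels
    return FeatureTable(X, labels)


@pytest.fixture(scope="session")
def benign_phantom():
    return generate_phantom("benign", 128, seed=21)


@pytest.fixture(scope="session")
def malignant_phantom():
    return generate_phantom("malignant", 128, seed=22)
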