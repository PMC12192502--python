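import numpy as np
import pytest

import spermfusion as sf


@pytest.fixture(scope="session")
def balanced6():
    """Well-separated 6-class, 3-view synthetic dataset (small, separable)."""
    spec = sf.SyntheticSpec(
        n_classes=6,
        views=(("v2s", 16), ("v2m", 16), ("v2l", 16)),
        separation=8.0,
        view_correlation=0.5,
        class_proportions=np.full(6, 1 / 6),
        n_samples=600,
        seed=101,
    )
    return sf.generate_synthetic_features(spec)


@pytest.fixture(scope="session")
def hi_lab_table():
    return sf.hi_lab_class_table()


def nearest_centroid_accuracy(X_train, y_train, X_test, y_test):
    """Independent oracle: classify by nearest class centroid."""
    classes = np.unique(y_train)
    centroids = np.stack([X_train[y_train == c].mean(axis=0) for c in classes])
    d = ((X_test[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = classes[np.argmin(d, axis=1)]
    return float(np.mean(pred == y_test))
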