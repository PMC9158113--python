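import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def blobs_rng():
    """Separate stream for well-separated test blobs."""
    return np.random.default_rng(77)


def make_blobs(centroids, n_per, scale, rng):
    """Tiny gaussian-blob generator used as test scaffolding."""
    centroids = np.asarray(centroids, dtype=float)
    X, labels = [], []
    for i, c in enumerate(centroids):
        X.append(c + scale * rng.standard_normal((n_per, centroids.shape[1])))
        labels.append(np.full(n_per, i))
    return np.vstack(X), np.concatenate(labels)
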