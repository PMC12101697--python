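import dataclasses

import numpy as np
import pytest

from heartcouple import EmbeddingConfig, SimParams, SpectralConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_params():
    """Short recording parameters so per-test generation stays cheap."""
    return SimParams(fs=2000.0, duration=2.0, seed=7)


@pytest.fixture
def fast_emb():
    """Small entropy crop: keeps the O(N^2) features fast in unit tests."""
    return EmbeddingConfig(max_points=300)


@pytest.fixture
def fast_spec():
    return SpectralConfig(window_length=256, overlap_fraction=0.5, band=(4.85, 900.0))


@pytest.fixture
def abnormal_recording(fast_params):
    return generate_recording(fast_params, "abnormal")


@pytest.fixture
def normal_recording(fast_params):
    return generate_recording(fast_params, "normal")


def make_blob_features(n_per_class=20, n_features=10, n_informative=2, sep=3.0, seed=0):
    """Two-Gaussian-blob FeatureMatrix helper for selection/classifier tests."""
    from heartcouple import FeatureMatrix

    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x1 = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    x1[:, :n_informative] += sep
    values = np.vstack([x0, x1])
    labels = np.array(["normal"] * n_per_class + ["abnormal"] * n_per_class)
    names = [f"f{i}" for i in range(n_features)]
    return FeatureMatrix(values=values, names=names, labels=labels)
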