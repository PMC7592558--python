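import numpy as np
import pytest

from imbtox.data_prep import FeatureMatrix
from imbtox.synthetic import SyntheticAssayConfig, generate_assay


@pytest.fixture
def small_assay() -> FeatureMatrix:
    """Small imbalanced assay for fast resampling/ensemble tests."""
    return generate_assay(
        SyntheticAssayConfig(n_total=200, ir=5, p=64, n_minority_clusters=2, seed=42)
    )


@pytest.fixture
def separable_assay() -> FeatureMatrix:
    """Fully separable classes: zero overlap, zero noise, one cluster."""
    return generate_assay(
        SyntheticAssayConfig(
            n_total=200, ir=5, p=64, n_minority_clusters=1,
            overlap=0.0, bit_flip_noise=0.0, seed=7,
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
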