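import numpy as np
import pytest

from fundusml.datatypes import ClassSpec
from fundusml.synthetic import generate_feature_dataset, generate_image_dataset


@pytest.fixture(scope="session")
def separable_features():
    """Three well-separated Gaussian classes, 20 samples each."""
    return generate_feature_dataset(n_classes=3, n_per_class=20, dim=16,
                                    separation=10.0, seed=11)


@pytest.fixture(scope="session")
def moderate_features():
    """Five moderately separable classes for ranking/CV tests."""
    return generate_feature_dataset(n_classes=5, n_per_class=24, dim=32,
                                    separation=2.0, seed=7)


@pytest.fixture(scope="session")
def tiny_images():
    """Two normal + two BDR 64x64 images."""
    specs = [
        ClassSpec(0, "normal", "none", 0.0),
        ClassSpec(1, "BDR", "dark_dots", 5.0),
    ]
    return generate_image_dataset(specs, n_per_class=2, image_size=(64, 64), seed=5)
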