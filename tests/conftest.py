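import numpy as np
import pytest
from hypothesis import settings

from snakeshot import data as sdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 4-class dataset shared by unit tests (fast to generate)."""
    return sdata.generate_dataset(n_classes=4, images_per_class=6, seed=11,
                                  image_size=96, regime_prob=0.15)


@pytest.fixture(scope="session")
def shape_classes():
    return sdata.default_shape_classes(12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_simple_polygon(rng, n_vertices=12, radius=20.0, center=(32.0, 32.0)):
    """Random star-shaped (hence simple) polygon for rasterization oracles."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    r = rng.uniform(0.3, 1.0, n_vertices) * radius
    return np.stack([center[0] + r * np.cos(theta),
                     center[1] + r * np.sin(theta)], axis=1)
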