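import numpy as np
import pytest

from lumenfit.geometry import ContourSpline
from lumenfit.synth import DatasetConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def round_spline():
    """Near-circular contour comfortably inside the default 15x15 extent."""
    return ContourSpline(d=np.full(10, 0.4), R=11.0, delta_s=1.0)


@pytest.fixture
def random_splines(rng):
    """Twenty random interior contours with the default configuration."""
    return [ContourSpline(d=rng.uniform(0.15, 0.55, 10)) for _ in range(20)]


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-example noiseless synthetic dataset shared across tests."""
    return generate_dataset(DatasetConfig(n_images=60, seed=11))
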