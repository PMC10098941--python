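import numpy as np
import pytest

from wtm import SceneSpec, WeibullParams, generate_seafloor_image


@pytest.fixture
def rng():
    return np.random.default_rng(20230328)


@pytest.fixture(scope="session")
def scene_image():
    """A default synthetic seafloor frame used across modules."""
    return generate_seafloor_image(SceneSpec(seed=7))


@pytest.fixture(scope="session")
def scene_image_small():
    return generate_seafloor_image(
        SceneSpec(height=64, width=64, texture=WeibullParams(1.0, 3.5), seed=11)
    )


def random_pdf(rng, n_bins=256, concentration=1.0):
    """A random probability vector (Dirichlet draw)."""
    return rng.dirichlet(np.full(n_bins, concentration))
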