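import numpy as np
import pytest
from hypothesis import settings

import afmflatten as af

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scene():
    """A fully distorted 128x128 scene with known ground truth."""
    return af.standard_scene(seed=5, rows=128, cols=128, n_spheres=6, radius_range=(5, 18))


@pytest.fixture(scope="session")
def standard_scene_seed1():
    """One full-size standard scene (256x256, all distortions)."""
    return af.standard_scene(seed=1)


@pytest.fixture(scope="session")
def processed_seed1(standard_scene_seed1):
    return af.process_image(standard_scene_seed1.image)
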