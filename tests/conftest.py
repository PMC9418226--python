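import numpy as np
import pytest

from fafseg.synthetic import LesionSpec, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene used by several read-only tests."""
    return generate_scene(SceneSpec(canvas_size=(128, 128), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_random_mask_pair(rng, shape=(16, 16), p=0.4):
    pred = (rng.random(shape) < p).astype(np.uint8)
    gt = (rng.random(shape) < p).astype(np.uint8)
    return pred, gt
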