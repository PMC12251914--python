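import numpy as np
import pytest

from yolo_ifsc.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 320x320 scene with 4 birds."""
    return generate_scene(SceneSpec(4, (0, 5, 11, 23), image_size=320, seed=7))
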