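import numpy as np
import pytest

from macuseg import SceneSpec, make_scene, scatter_macules


@pytest.fixture(scope="session")
def default_scene():
    """Macule-free leg scene at default parameters, seed 0."""
    return make_scene(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def petechiae_scene():
    """Uniform-tone leg with 10 petechiae painted at factor (0.95, 0.90, 0.87)."""
    rng = np.random.default_rng(7)
    shape = (320, 240)
    specs = scatter_macules("petechiae", 10, shape, rng)
    spec = SceneSpec(shape=shape, seed=7, illumination=0.0, macules=specs)
    img, truth = make_scene(spec)
    return spec, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
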