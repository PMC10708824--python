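import numpy as np
import pytest

from nirfuse import RegisteredPair, SceneSpec, generate_scene


def random_pair(rng: np.random.Generator, h: int, w: int) -> RegisteredPair:
    return RegisteredPair(vis=rng.random((h, w, 3)), nir=rng.random((h, w)))


@pytest.fixture(scope="session")
def underexposed_scene():
    """One deterministic strongly underexposed scene with truth."""
    return generate_scene(SceneSpec(seed=11, exposure=0.2))


@pytest.fixture(scope="session")
def normal_scene():
    """The same geometry as ``underexposed_scene`` at full exposure."""
    return generate_scene(SceneSpec(seed=11, exposure=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
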