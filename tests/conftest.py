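import numpy as np
import pytest

from nightgrape import SceneSpec, default_templates, generate_scene


@pytest.fixture(scope="session")
def scene():
    """One default synthetic vineyard scene with ground truth."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def scene_templates(scene):
    return default_templates(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
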