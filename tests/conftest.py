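import numpy as np
import pytest

from nutriseg.synthetic import SceneConfig, generate_dishes


@pytest.fixture(scope="session")
def small_scene_config():
    return SceneConfig(image_size=(64, 64), seed=123)


@pytest.fixture(scope="session")
def small_dishes(small_scene_config):
    """A dozen noiseless 64x64 synthetic dishes shared across tests."""
    return generate_dishes(small_scene_config, 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
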