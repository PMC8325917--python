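import numpy as np
import pytest

from treefuse.synthetic_scene import SceneConfig, generate_plot, make_archetypes


@pytest.fixture(scope="session")
def archetypes5():
    return make_archetypes(5, seed=11)


@pytest.fixture(scope="session")
def small_scene_config():
    return SceneConfig(n_taxa=5, seed=11)


@pytest.fixture(scope="session")
def small_plot(small_scene_config, archetypes5):
    return generate_plot(small_scene_config, archetypes5, seed=21)


@pytest.fixture(scope="session")
def zero_noise_plot(archetypes5):
    cfg = SceneConfig(n_taxa=5, spectral_noise=0.0, color_noise=0.0, seed=11)
    return generate_plot(cfg, archetypes5, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
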