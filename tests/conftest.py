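import numpy as np
import pytest

from vegindex import SceneConfig, default_profiles, simulate_scene


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_scene(profiles):
    """A seeded default-noise scene: 4 plots per class on an 80x80 grid."""
    cfg = SceneConfig(shape=(80, 80), plots_per_class=4, seed=7)
    return simulate_scene(profiles, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
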