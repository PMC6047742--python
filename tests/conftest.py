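import numpy as np
import pytest

from cristadyn import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """Small noiseless textured scene shared across fast tests."""
    cfg = SceneConfig(
        size=128,
        n_mitochondria=3,
        frame_count=8,
        texture_motion_fraction=0.07,
        noise_sigma=0.0,
        bleach_rate=0.0,
        seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
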