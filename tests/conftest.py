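import numpy as np
import pytest

from aoslo.synthetic import MotionConfig, SceneConfig, generate_scene


def small_scene_config(**overrides) -> SceneConfig:
    """A compact scene that keeps test runtimes low while preserving
    the statistical structure (cone mosaic, vessel, particles)."""
    defaults = dict(width_px=96, height_px=96, n_frames=4, rng_seed=7)
    defaults.update(overrides)
    return SceneConfig(**defaults)


def still_motion(**overrides) -> MotionConfig:
    defaults = dict(
        rigid_translation_sd_px=0.0,
        rigid_rotation_sd_deg=0.0,
        intraframe_warp_amplitude_px=0.0,
    )
    defaults.update(overrides)
    return MotionConfig(**defaults)


@pytest.fixture(scope="session")
def cone_phantom():
    """A 128x128 motion-free cone-mosaic image with a vessel shadow —
    textured enough for intensity-based registration."""
    cfg = SceneConfig(width_px=128, height_px=128, n_frames=2, rng_seed=1)
    return generate_scene(cfg).base_image


@pytest.fixture(scope="session")
def small_phantom():
    cfg = SceneConfig(width_px=96, height_px=96, n_frames=2, rng_seed=2)
    return generate_scene(cfg).base_image


@pytest.fixture
def rng():
    return np.random.default_rng(42)
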