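import numpy as np
import pytest

from saffpick.nn.model import ModelConfig
from saffpick.synth import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Small but structurally complete network for fast tests."""
    return ModelConfig(
        width_multiplier=0.5,
        stage_repeats=(1, 1, 1),
        aspp_bottleneck=16,
        aspp_out=64,
        decoder_channels=32,
    )


@pytest.fixture
def clean_scene():
    """One zero-noise vertical-branch scene at full resolution."""
    return generate_scene(
        SceneSpec(seed=11, noise_sigma=0.0, branch_angle_deg=0.0)
    )


def small_scenes(n, scale=0.2, noise=0.0, seed0=0):
    """Reduced-resolution scenes for network training tests."""
    return [
        generate_scene(SceneSpec(seed=seed0 + i, noise_sigma=noise).scaled(scale))
        for i in range(n)
    ]


@pytest.fixture
def scene_batch():
    return small_scenes(8)
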