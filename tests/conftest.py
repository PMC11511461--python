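import numpy as np
import pytest

from pupilgaze.config import NetConfig, SynthEyeConfig


@pytest.fixture
def clean_config() -> SynthEyeConfig:
    """Synthetic config with every nuisance disabled: the mask, centroid
    and rasterization oracles need uncorrupted geometry."""
    return SynthEyeConfig(
        noise_sigma=0.0,
        glint_count_range=(0, 0),
        illumination_gradient_range=(0.0, 0.0),
        closed_prob=0.0,
        partial_occlusion_prob=0.0,
    )


@pytest.fixture
def small_net() -> NetConfig:
    return NetConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
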