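import numpy as np
import pytest

from maskcycle.fixtures import DomainShift, FixtureConfig, make_annotated_frame


@pytest.fixture
def small_config():
    """64x64 fixture recipe used throughout the desk-scale tests."""
    return FixtureConfig(
        seed=7, image_height=64, image_width=64,
        blobs_per_frame=(3, 8), blob_axes=(4.0, 10.0), texture_scale=12.0,
        n_background_frames=3, n_real_frames=5, n_test_frames=2,
        domain_shift=DomainShift(hue_shift=50.0, blur_sigma=1.5, noise_sd=0.05))


@pytest.fixture
def annotated_sample(small_config):
    return make_annotated_frame(small_config, np.random.default_rng(7))
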