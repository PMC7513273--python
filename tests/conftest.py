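import numpy as np
import pytest

from angioseg.network import NetworkConfig, STNet
from angioseg.simulate import VesselTreeSpec, render_sequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net():
    """Small N=1 network shared by read-only tests."""
    cfg = NetworkConfig(n=1, input_size=64, width_multiplier=0.25)
    return STNet(cfg, seed=0)


@pytest.fixture(scope="session")
def clean_sequence():
    """Noise-free, occlusion-free clip with contrast present from frame 0."""
    spec = VesselTreeSpec(seed=3, image_size=64, frame_count=8,
                          n_branches=3, occlusion_rate=0.0,
                          gaussian_sigma=0.0, poisson_scale=0.0,
                          contrast_arrival=[0, 0, 0])
    return render_sequence(spec)
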