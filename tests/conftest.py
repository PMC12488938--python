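import numpy as np
import pytest

from epiquant import (
    ChannelMeta,
    EmbryoSimConfig,
    ImageStack,
    gen_embryo_stack,
)


@pytest.fixture(scope="session")
def small_embryo():
    """Noiseless 32^3 stack with 8 nuclei; shared read-only across tests."""
    cfg = EmbryoSimConfig(
        grid_shape=(32, 32, 32),
        n_nuclei=8,
        nucleus_radius_um=(2.5, 3.5),
        noise_sd=0.0,
        seed=7,
    )
    return cfg, *gen_embryo_stack(cfg)


@pytest.fixture()
def flat_stack():
    """Tiny stack with a known constant channel, no attenuation applied."""
    data = np.full((1, 4, 5, 5), 100.0)
    return ImageStack(
        data=data, channels=[ChannelMeta("DAPI", 0.014)], voxel_spacing_um=(10.0, 1.0, 1.0)
    )
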