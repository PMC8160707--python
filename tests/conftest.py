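import numpy as np
import pytest

from rawphot import SpotModel, desk_spot


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spot():
    """A tiny fast spot for unit tests of the rendering chain."""
    return SpotModel(width=160, height=120, center=(60.0, 80.0), sigma=40.0, seed=42)


@pytest.fixture
def quiet_small_spot():
    """Same geometry with all noise sources off (deterministic chain checks)."""
    return SpotModel(
        width=160, height=120, center=(60.0, 80.0), sigma=40.0,
        read_noise_sd=0.0, shot_noise=False, seed=42,
    )


@pytest.fixture
def standard_spot():
    """Reduced-geometry spot under the standard illumination/noise conditions."""
    return desk_spot(seed=20210520)
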