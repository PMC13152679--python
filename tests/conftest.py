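import numpy as np
import pytest

from dopamap.io import Trace
from dopamap.synthetic import SyntheticConfig, generate_hotspot_fixture, generate_wave_fixture


@pytest.fixture(scope="session")
def striatal_fixture():
    """Three-trial evoked-release fixture with known hotspot squares."""
    cfg = SyntheticConfig(seed=7)
    movies, truth = generate_hotspot_fixture(cfg)
    return movies, truth


@pytest.fixture(scope="session")
def retinal_fixture():
    """Dual-channel spontaneous-wave fixture: 20 waves, 45 s apart."""
    fr = 1.47
    wave_frames = tuple(50 + int(round(i * 45 * fr)) for i in range(20))
    cfg = SyntheticConfig(n_frames=wave_frames[-1] + 60, seed=3)
    ca, nir, truth = generate_wave_fixture(cfg, wave_frames)
    return ca, nir, truth


@pytest.fixture
def flat_trace():
    return Trace(np.full(100, 5.0), frame_rate=2.0)
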