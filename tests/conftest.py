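import numpy as np
import pytest

from servechain import synth
from servechain.kinematics import GyroTrace


@pytest.fixture(scope="session")
def population():
    return synth.default_population_params()


@pytest.fixture(scope="session")
def quiet_population():
    """Noise-free population for exact round-trip checks."""
    return synth.default_population_params(noise_sd_dps=0.0)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest useful paired cohort: 2 players x 3 first/second pairs."""
    return synth.GenerationConfig(n_players=2, serves_per_type=3, drop_rate=0.0)


def make_trace(w, segment="pelvis", fs_hz=1000.0, clipped=None):
    w = np.asarray(w, dtype=float)
    t = np.arange(w.shape[0]) * (1000.0 / fs_hz)
    return GyroTrace(segment, fs_hz, t, w, clipped)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
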