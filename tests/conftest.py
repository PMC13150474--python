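import numpy as np
import pytest

from spikesusc import exemplar_punit, exemplar_punit_mid
from spikesusc.punit_model import SpikeData


@pytest.fixture(scope="session")
def low_cv_cell():
    """Reference low-CV P-unit model (rate ~76 Hz, CV ~0.21)."""
    return exemplar_punit()


@pytest.fixture(scope="session")
def mid_cv_cell():
    """Reference mid-CV P-unit model (rate ~227 Hz, CV ~0.78)."""
    return exemplar_punit_mid()


@pytest.fixture()
def periodic_spikes():
    """Perfectly periodic 100 Hz train over 10 s (ISIs exactly 10 ms)."""
    t = np.arange(0.005, 10.0, 0.01)
    return SpikeData(trials=[t], duration_s=10.0)


@pytest.fixture()
def poisson_spikes():
    """Homogeneous Poisson train with ~1e4 ISIs."""
    rng = np.random.default_rng(123)
    isis = rng.exponential(1.0 / 200.0, 11000)
    t = np.cumsum(isis)
    dur = 10500 / 200.0
    return SpikeData(trials=[t[t <= dur]], duration_s=dur)
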