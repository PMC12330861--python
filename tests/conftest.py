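import numpy as np
import pytest

from alphaflux.containers import RegionTimeSeries
from alphaflux.synth import SynthSpec


@pytest.fixture(scope="session")
def fast_spec():
    """Short, low-rate spec keeping Morlet/TFR tests cheap; fs = 250 Hz
    still supports the full 2-40 Hz analysis grid."""
    return SynthSpec(duration=60.0, fs=250.0, iaf=10.0, alpha_gain=1.0,
                     aperiodic_gain=0.3, aperiodic_exponent=1.0, seed=11)


@pytest.fixture(scope="session")
def tone_ts():
    """30 s unit-amplitude 10 Hz tone at 250 Hz."""
    fs = 250.0
    t = np.arange(0, 30.0, 1.0 / fs)
    return RegionTimeSeries(np.sin(2 * np.pi * 10.0 * t)[None, :], fs=fs,
                            labels=["tone"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
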