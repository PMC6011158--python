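import numpy as np
import pytest

from cautoreg.signal_io import SignalRecord
from cautoreg.synthetic_data import AutoregModel, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_record():
    """A 300-s two-channel record at 50 Hz with known structure."""
    fs = 50.0
    t = np.arange(round(300 * fs)) / fs
    abp = 90.0 + 2.0 * np.sin(2 * np.pi * 0.05 * t) + 1.0 * np.sin(2 * np.pi * 0.1 * t)
    cbfv = 50.0 + 1.5 * np.sin(2 * np.pi * 0.05 * t + 0.3)
    return SignalRecord(
        time_s=t, abp=abp, cbfv=cbfv, fs=fs, meta={"condition": "baseline"}
    )


@pytest.fixture
def fast_config():
    """Generator config downsampled for test speed (50 Hz, 330 s)."""
    return SyntheticConfig(fs=50.0, duration_s=330.0, seed=7)


@pytest.fixture
def noiseless_config():
    return SyntheticConfig(fs=50.0, duration_s=330.0, seed=7, model=AutoregModel(noise_cv=0.0))
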