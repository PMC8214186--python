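import numpy as np
import pytest

from pulsefit.config import HrConfig
from pulsefit.ppg import ChannelSeries, preprocess, resample_uniform, split_windows
from pulsefit.simulate import ConstantHR, PpgSimSpec, simulate_ppg


@pytest.fixture
def hr_config() -> HrConfig:
    return HrConfig()


def make_series(values: np.ndarray, rate: float = 60.0) -> ChannelSeries:
    """Wrap one signal into all three channels of a ChannelSeries."""
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) / rate
    return ChannelSeries(t, values.copy(), values.copy(), values.copy(), rate)


def clean_window(bpm: float, seconds: float = 10.0, rate: float = 60.0,
                 noise_sd: float = 0.0, seed: int = 0,
                 config: HrConfig | None = None) -> ChannelSeries:
    """One preprocessed analysis window of synthetic PPG at a known rate."""
    config = config or HrConfig()
    spec = PpgSimSpec(duration=seconds, rate=rate, hr_profile=ConstantHR(bpm),
                      noise_sd=noise_sd, seed=seed)
    series, _ = simulate_ppg(spec)
    filtered = preprocess(resample_uniform(series), config.band)
    return split_windows(filtered, seconds)[0]
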