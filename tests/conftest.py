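import numpy as np
import pytest
from scipy import signal as sps

from pabr.response_extraction import DEFAULT_LAG_WINDOW_S, ResponseWaveform

EEG_FS = 10_000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_noise_waveform(
    rng: np.random.Generator,
    std: float = 1.0,
    fs: float = EEG_FS,
    lag_window_s: tuple[float, float] = DEFAULT_LAG_WINDOW_S,
    band_limited: bool = True,
) -> ResponseWaveform:
    """A noise-only averaged-response surrogate on the standard lag axis."""
    n = int(round((lag_window_s[1] - lag_window_s[0]) * fs))
    if band_limited:
        sos = sps.butter(1, [30, 2000], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfilt(sos, rng.standard_normal(2 * n))[-n:]
        x *= std / x.std()
    else:
        x = rng.standard_normal(n) * std
    return ResponseWaveform(w=x, fs_hz=fs, lag_start_s=lag_window_s[0], n_stimuli=1000)
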