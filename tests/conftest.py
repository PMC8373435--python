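import numpy as np
import pytest

from brs_eeg.config_io import DEFAULT_MONTAGE, Recording


@pytest.fixture(scope="session")
def montage():
    return DEFAULT_MONTAGE


def make_recording(
    samples: np.ndarray,
    rate: float = 500.0,
    channels=None,
    participant: str = "P01",
    group: str = "unknown",
    run: int = 1,
) -> Recording:
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return Recording(
        participant=participant, group=group, run=run,
        samples=samples, rate=rate, channels=channels,
    )


def sine_recording(
    freq_hz: float,
    duration_s: float = 90.0,
    rate: float = 500.0,
    n_channels: int = 1,
    amplitude: float = 1.0,
    channels=None,
) -> Recording:
    t = np.arange(int(round(duration_s * rate))) / rate
    row = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return make_recording(
        np.tile(row, (n_channels, 1)), rate=rate, channels=channels
    )
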