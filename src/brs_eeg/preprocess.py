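"""Band-pass filtering, overlapping epoch segmentation, and epoch rejection.

The preprocessing chain for each run is: zero-phase FIR band-pass
(0.5–50 Hz by default), segmentation into fixed-length overlapping epochs
(6 s with 60 % overlap by default, so a 90 s run yields 36 epochs), and
automatic rejection of epochs containing large-amplitude excursions
(default ±100 µV), which stands in for manual inspection of artifactual
segments.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
from scipy import signal

from .config_io import Recording


class ParameterError(ValueError):
    """Invalid preprocessing parameter."""


@dataclasses.dataclass
class EpochArray:
    """Fixed-length epochs for one participant-run.

    ``data`` has shape (n_epochs, n_channels, n_samples) in microvolts.
    ``kept`` records the original epoch indices that survive rejection, in
    order.
    """

    participant: str
    run: int
    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    epoch_s: float
    overlap: float
    kept: tuple[int, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError("epoch data must be (epochs, channels, samples)")
        self.channels = tuple(self.channels)
        self.kept = tuple(int(k) for k in self.kept)
        if len(self.kept) != self.data.shape[0]:
            raise ParameterError("kept-index list must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@functools.lru_cache(maxsize=64)
def design_bandpass(
    low: float, high: float, rate: float, *, max_group_delay_s: float = 0.5
) -> np.ndarray:
    """Design a windowed-sinc (Hamming) FIR band-pass filter.

    The number of taps is odd and chosen so the one-way group delay is at
    most ``max_group_delay_s`` (501 taps at 500 Hz). The filter is intended
    for forward–backward application, giving zero phase and a squared
    magnitude response.
    """
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rate / 2:
        raise ParameterError(
            f"high cutoff {high} Hz must be below the Nyquist frequency {rate / 2} Hz"
        )
    numtaps = 2 * int(round(max_group_delay_s * rate)) + 1
    numtaps = max(numtaps, 9)
    return signal.firwin(
        numtaps, [low, high], fs=rate, pass_zero=False, window="hamming"
    )


def bandpass_filter(rec: Recording, low: float = 0.5, high: float = 50.0) -> Recording:
    """Zero-phase FIR band-pass per channel; output length equals input."""
    taps = design_bandpass(low, high, rec.rate)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    filtered = signal.filtfilt(taps, [1.0], rec.samples, axis=-1, padlen=padlen)
    return Recording(
        participant=rec.participant,
        group=rec.group,
        run=rec.run,
        samples=filtered,
        rate=rec.rate,
        channels=rec.channels,
    )


def epoch_count(total_samples: int, epoch_samples: int, step_samples: int) -> int:
    """Closed-form count of full epochs: floor((T − L)/step) + 1, 0 if T < L."""
    if total_samples < epoch_samples:
        return 0
    return (total_samples - epoch_samples) // step_samples + 1


def segment_epochs(
    rec: Recording, epoch_s: float = 6.0, overlap: float = 0.6
) -> EpochArray:
    """Segment a run into fixed-length overlapping epochs.

    Epochs start at multiples of ``step = round(epoch_s * (1 − overlap) *
    rate)`` samples; trailing data shorter than one epoch is discarded.
    A 90 s run at 500 Hz with 6 s epochs and 60 % overlap yields 36 epochs.
    """
    if not (0 <= overlap < 1):
        raise ParameterError(f"overlap must be in [0, 1), got {overlap}")
    length = int(round(epoch_s * rec.rate))
    if length < 2:
        raise ParameterError("epoch length must cover at least 2 samples")
    step = int(round(epoch_s * (1 - overlap) * rec.rate))
    step = max(step, 1)
    n = epoch_count(rec.n_samples, length, step)
    if n < 1:
        raise ParameterError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{length}-sample epoch"
        )
    starts = np.arange(n) * step
    data = np.stack([rec.samples[:, s : s + length] for s in starts])
    return EpochArray(
        participant=rec.participant,
        run=rec.run,
        data=data,
        rate=rec.rate,
        channels=rec.channels,
        epoch_s=epoch_s,
        overlap=overlap,
        kept=tuple(range(n)),
    )


def reject_epochs(
    ep: EpochArray,
    amp_threshold: float = 100.0,
    channels: tuple[str, ...] | None = None,
) -> EpochArray:
    """Drop epochs whose absolute amplitude exceeds ``amp_threshold`` µV.

    The check runs on ``channels`` if given (e.g. the montage electrodes),
    else on every channel. Epoch order is preserved and surviving original
    indices are recorded in ``kept``.
    """
    if not amp_threshold > 0:
        raise ParameterError("amplitude threshold must be positive")
    if channels is None:
        idx = np.arange(len(ep.channels))
    else:
        idx = np.array([ep.channels.index(c) for c in channels])
    peak = np.abs(ep.data[:, idx, :]).max(axis=(1, 2))
    keep = peak <= amp_threshold
    if not keep.any():
        raise ParameterError(
            f"all {ep.n_epochs} epochs exceed {amp_threshold} µV; "
            "review the rejection threshold"
        )
    return EpochArray(
        participant=ep.participant,
        run=ep.run,
        data=ep.data[keep],
        rate=ep.rate,
        channels=ep.channels,
        epoch_s=ep.epoch_s,
        overlap=ep.overlap,
        kept=tuple(np.asarray(ep.kept)[keep]),
    )


def preprocess_run(
    rec: Recording,
    *,
    low: float = 0.5,
    high: float = 50.0,
    epoch_s: float = 6.0,
    overlap: float = 0.6,
    amp_threshold: float = 100.0,
    reject_channels: tuple[str, ...] | None = None,
) -> EpochArray:
    """Full chain: band-pass → segment → reject, with the default settings."""
    filtered = bandpass_filter(rec, low, high)
    epochs = segment_epochs(filtered, epoch_s, overlap)
    return reject_epochs(epochs, amp_threshold, reject_channels)
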