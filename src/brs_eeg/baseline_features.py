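"""Single-run comparison features: spectral power, Katz fractal dimension,
and band-limited magnitude-squared coherence.

These are the conventional resting-state EEG features against which the
between-run similarity is benchmarked. All three are computed from the
epochs of a single run (run 1 by convention): per-epoch values are computed
first and then averaged across epochs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .brs_features import FeatureError, epoch_band_power
from .config_io import Band, BandScheme, DEFAULT_BANDS, Montage
from .preprocess import EpochArray


def _band_edges(band: Band | tuple[float, float]) -> tuple[float, float]:
    return (band.low, band.high) if isinstance(band, Band) else (float(band[0]), float(band[1]))


# ---------------------------------------------------------------------------
# Spectral power
# ---------------------------------------------------------------------------

def singlerun_spectral_power(
    ep: EpochArray,
    montage: Montage,
    region: str,
    band: Band | str | tuple[float, float],
    bands: BandScheme = DEFAULT_BANDS,
) -> np.ndarray:
    """Per-electrode band power averaged over epochs.

    For each electrode of ``region``: compute the band power of every epoch,
    then average across epochs. Returns one value per electrode in montage
    order (e.g. 7 values for the default frontal region).
    """
    if isinstance(band, str):
        band = bands[band]
    low, high = _band_edges(band)
    electrodes = montage.electrodes(region)
    out = np.empty(len(electrodes))
    for k, e in enumerate(electrodes):
        if e not in ep.channels:
            raise FeatureError(f"electrode {e!r} (region {region!r}) missing from data")
        ch = ep.channels.index(e)
        powers = [
            epoch_band_power(ep.data[i, ch], ep.rate, (low, high))
            for i in range(ep.n_epochs)
        ]
        out[k] = np.mean(powers)
    return out


# ---------------------------------------------------------------------------
# Katz fractal dimension
# ---------------------------------------------------------------------------

def katz_fd(series: np.ndarray) -> float:
    """Katz's fractal dimension of a waveform.

    The series is treated as a planar curve with unit abscissa spacing:
    total length ``L = sum_k sqrt(1 + (x_{k+1} - x_k)^2)``, maximal
    excursion from the first point ``d = max_k sqrt(k^2 + (x_k - x_0)^2)``,
    and with ``n = N - 1`` segments

        KFD = log10(n) / (log10(n) + log10(d / L)).

    Any affine series gives exactly 1 (d = L); a constant series is defined
    as 1 (a flat straight line). The estimate is invariant to adding a
    constant to the series.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise FeatureError("Katz FD needs a 1-D series of at least 3 samples")
    dx = np.diff(x)
    n = x.size - 1
    L = float(np.sum(np.sqrt(1.0 + dx * dx)))
    k = np.arange(1, x.size, dtype=np.float64)
    d = float(np.max(np.sqrt(k * k + (x[1:] - x[0]) ** 2)))
    if d == 0.0:  # constant series
        return 1.0
    denom = np.log10(n) + np.log10(d / L)
    if denom == 0.0:
        return 1.0
    return float(np.log10(n) / denom)


def singlerun_katz_fd(
    ep: EpochArray, montage: Montage, region: str
) -> np.ndarray:
    """Per-electrode Katz FD averaged over epochs (one value per electrode)."""
    electrodes = montage.electrodes(region)
    out = np.empty(len(electrodes))
    for k, e in enumerate(electrodes):
        if e not in ep.channels:
            raise FeatureError(f"electrode {e!r} (region {region!r}) missing from data")
        ch = ep.channels.index(e)
        out[k] = np.mean([katz_fd(ep.data[i, ch]) for i in range(ep.n_epochs)])
    return out


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    band: Band | tuple[float, float],
    *,
    seg_s: float = 1.0,
    seg_overlap: float = 0.5,
) -> float:
    """Magnitude-squared coherence of two signals averaged over a band.

    Welch cross-spectra are estimated from Hann-tapered sub-windows
    (``seg_s`` seconds, ``seg_overlap`` fractional overlap) inside the
    epoch, and the resulting coherence is averaged over the frequency bins
    in ``[low, high)``. At least two sub-windows are required: coherence of
    a single segment is identically 1 and carries no information.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise FeatureError("signals must be 1-D arrays of equal length")
    low, high = _band_edges(band)
    if not (0 <= low < high <= rate / 2):
        raise FeatureError(f"band ({low}, {high}) must lie within (0, {rate / 2})")
    nperseg = int(round(seg_s * rate))
    noverlap = int(round(nperseg * seg_overlap))
    step = nperseg - noverlap
    n_seg = 0 if x.size < nperseg else 1 + (x.size - nperseg) // step
    if n_seg < 2:
        raise FeatureError(
            f"signal of {x.size} samples gives {n_seg} sub-window(s); "
            "coherence needs at least 2"
        )
    freqs, cxy = signal.coherence(
        x, y, fs=rate, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    sel = (freqs >= low) & (freqs < high)
    if not sel.any():
        raise FeatureError(f"band [{low}, {high}) contains no coherence bins")
    return float(np.mean(cxy[sel]))


def electrode_pairs(montage: Montage, region: str) -> list[tuple[str, str]]:
    """Unordered electrode pairs of a region, lexicographic by montage order."""
    electrodes = montage.electrodes(region)
    if len(electrodes) < 2:
        raise FeatureError(
            f"region {region!r} has {len(electrodes)} electrode(s); "
            "coherence needs at least 2"
        )
    return [
        (electrodes[i], electrodes[j])
        for i in range(len(electrodes))
        for j in range(i + 1, len(electrodes))
    ]


def coherence_feature_vector(
    ep: EpochArray,
    montage: Montage,
    region: str,
    band: Band | str | tuple[float, float],
    bands: BandScheme = DEFAULT_BANDS,
    *,
    seg_s: float = 1.0,
    seg_overlap: float = 0.5,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Per-pair band coherence averaged over epochs.

    One feature per unordered electrode pair of the region — n_e(n_e−1)/2
    values (21 for a 7-electrode region). Per-epoch coherences are computed
    separately and then averaged across epochs.
    """
    if isinstance(band, str):
        band = bands[band]
    pairs = electrode_pairs(montage, region)
    for e in montage.electrodes(region):
        if e not in ep.channels:
            raise FeatureError(f"electrode {e!r} (region {region!r}) missing from data")
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        ia, ib = ep.channels.index(a), ep.channels.index(b)
        vals = [
            band_coherence(
                ep.data[i, ia], ep.data[i, ib], ep.rate, band,
                seg_s=seg_s, seg_overlap=seg_overlap,
            )
            for i in range(ep.n_epochs)
        ]
        out[k] = np.mean(vals)
    return out, pairs
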