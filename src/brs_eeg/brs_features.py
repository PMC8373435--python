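"""Between-run similarity (BRS) of regional spectral-power vectors.

The statistic quantifies how much the spectral structure of resting-state
EEG changes between two recording runs of the same participant (e.g. before
and after a demanding cognitive task). For one scalp region:

1. each kept epoch of each run yields a band-power vector (one component per
   band, region-averaged over electrodes);
2. every run-1 epoch is paired with every run-2 epoch and scored by the
   reciprocal Euclidean distance between their vectors,
   ``s_ij = 1 / ||p_j(2) − p_i(1)||``;
3. the raw similarity ``S`` is the mean of all n × m pairwise scores;
4. ``S`` is standardized against the healthy-control (HC) group:
   ``S_std = (S − mean_HC) / std_HC``.

High BRS means the two runs look alike (low intra-subject variability);
clinically impaired groups are expected to sit below zero after HC
standardization.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import cdist

from .config_io import Band, BandScheme, DEFAULT_BANDS, DEFAULT_MONTAGE, Montage
from .preprocess import EpochArray

#: Floor on the pairwise Euclidean distance; reciprocal distances are capped
#: at 1/EPS so coincident power vectors give a finite similarity.
EPS = 1e-12


class FeatureError(ValueError):
    """Invalid input to a feature computation."""


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------

def _band_bins(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    sel = (freqs >= low) & (freqs < high)
    if not sel.any():
        raise FeatureError(
            f"band [{low}, {high}) Hz contains no frequency bins "
            f"(resolution {freqs[1] - freqs[0]:g} Hz)"
        )
    return sel


def epoch_band_power(
    x: np.ndarray, rate: float, band: Band | tuple[float, float]
) -> float:
    """Band power (µV²) of one epoch of one channel.

    One-sided Hann-tapered periodogram of the demeaned epoch, integrated
    over bins ``low <= f < high`` (half-open, so shared band edges are
    counted once). A unit-amplitude sinusoid inside the band yields ≈ 0.5.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise FeatureError("epoch must be a 1-D array of at least 2 samples")
    low, high = (band.low, band.high) if isinstance(band, Band) else band
    if not (0 <= low < high <= rate / 2):
        raise FeatureError(f"band ({low}, {high}) must lie within (0, {rate / 2})")
    freqs, pxx = signal.periodogram(
        x, fs=rate, window="hann", detrend="constant", scaling="density"
    )
    df = freqs[1] - freqs[0]
    sel = _band_bins(freqs, low, high)
    return float(pxx[sel].sum() * df)


@dataclasses.dataclass
class BandPowerTensor:
    """Per-epoch, per-electrode, per-band powers for one run.

    ``values`` has shape (n_epochs, n_electrodes, n_bands), all entries
    non-negative, in µV².
    """

    participant: str
    run: int
    values: np.ndarray
    channels: tuple[str, ...]
    bands: BandScheme

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FeatureError("values must be (epochs, electrodes, bands)")
        if self.values.shape[2] != len(self.bands):
            raise FeatureError("band axis must match the band scheme")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


def band_power_tensor(ep: EpochArray, bands: BandScheme = DEFAULT_BANDS) -> BandPowerTensor:
    """Band powers for every kept epoch and channel of one run."""
    freqs, pxx = signal.periodogram(
        ep.data, fs=ep.rate, window="hann", detrend="constant",
        scaling="density", axis=-1,
    )
    df = freqs[1] - freqs[0]
    cols = []
    for band in bands:
        sel = _band_bins(freqs, band.low, band.high)
        cols.append(pxx[..., sel].sum(axis=-1) * df)
    values = np.stack(cols, axis=-1)
    return BandPowerTensor(
        participant=ep.participant,
        run=ep.run,
        values=values,
        channels=ep.channels,
        bands=bands,
    )


# ---------------------------------------------------------------------------
# Regional power vectors
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegionPowerSeries:
    """Per-epoch band-power vectors for one region of one run.

    ``vectors`` has shape (n_epochs, n_bands_selected); components follow the
    band-scheme order restricted to ``band_names``.
    """

    participant: str
    run: int
    region: str
    band_names: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise FeatureError("vectors must be (epochs, bands)")
        self.band_names = tuple(self.band_names)
        if self.vectors.shape[1] != len(self.band_names):
            raise FeatureError("vector dimension must match the selected bands")

    @property
    def n_epochs(self) -> int:
        return self.vectors.shape[0]


def _subset_indices(bands: BandScheme, band_subset: Iterable[str] | None) -> list[int]:
    if band_subset is None:
        return list(range(len(bands)))
    wanted = set(band_subset)
    idx = [i for i, name in enumerate(bands.names) if name in wanted]
    unknown = wanted - set(bands.names)
    if unknown:
        raise FeatureError(f"unknown bands {sorted(unknown)}; have {bands.names}")
    return idx


def region_power_series(
    bp: BandPowerTensor,
    montage: Montage,
    region: str,
    band_subset: Iterable[str] | None = None,
) -> RegionPowerSeries:
    """Region-mean power vectors: unweighted mean over the region's
    electrodes per epoch and band. ``band_subset`` restricts the vector to
    the named bands (e.g. a single band for per-band analyses)."""
    electrodes = montage.electrodes(region)
    rows = []
    for e in electrodes:
        if e not in bp.channels:
            raise FeatureError(f"electrode {e!r} (region {region!r}) missing from data")
        rows.append(bp.channels.index(e))
    idx = _subset_indices(bp.bands, band_subset)
    vectors = bp.values[:, rows, :].mean(axis=1)[:, idx]
    return RegionPowerSeries(
        participant=bp.participant,
        run=bp.run,
        region=region,
        band_names=tuple(bp.bands.names[i] for i in idx),
        vectors=vectors,
    )


# ---------------------------------------------------------------------------
# Between-run similarity
# ---------------------------------------------------------------------------

def pairwise_similarity_mean(v1: np.ndarray, v2: np.ndarray) -> float:
    """Mean reciprocal Euclidean distance over all n × m vector pairs."""
    v1 = np.atleast_2d(np.asarray(v1, dtype=np.float64))
    v2 = np.atleast_2d(np.asarray(v2, dtype=np.float64))
    if v1.shape[1] != v2.shape[1]:
        raise FeatureError(
            f"vector dimensions differ: {v1.shape[1]} vs {v2.shape[1]}"
        )
    if v1.shape[0] < 1 or v2.shape[0] < 1:
        raise FeatureError("each run needs at least one epoch vector")
    dist = cdist(v1, v2)
    return float(np.mean(1.0 / np.maximum(dist, EPS)))


def between_run_similarity(p1: RegionPowerSeries, p2: RegionPowerSeries) -> float:
    """Raw between-run similarity S for one region.

    Symmetric under swapping the runs; strictly positive; capped at 1/EPS
    when all vector pairs coincide.
    """
    if p1.region != p2.region:
        raise FeatureError(f"region mismatch: {p1.region!r} vs {p2.region!r}")
    if p1.band_names != p2.band_names:
        raise FeatureError("band subsets of the two runs differ")
    return pairwise_similarity_mean(p1.vectors, p2.vectors)


def standardize_brs(
    values: Mapping[str, float],
    hc_ids: Iterable[str],
    *,
    mode: str = "global",
    train_ids: Iterable[str] | None = None,
    ddof: int = 1,
) -> dict[str, float]:
    """HC-benchmarked standardization of raw similarities for one region.

    ``mode="global"`` (default) uses every HC participant as the reference
    distribution. ``mode="fold-train"`` restricts the reference to HCs inside
    ``train_ids``, the leakage-safe variant for cross-validation. The
    reference standard deviation uses ``ddof=1`` (sample) by default.
    """
    hc = set(hc_ids)
    if mode == "fold-train":
        if train_ids is None:
            raise FeatureError("fold-train standardization needs train_ids")
        hc &= set(train_ids)
    elif mode != "global":
        raise FeatureError(f"unknown standardization mode {mode!r}")
    ref = [values[p] for p in values if p in hc]
    if len(ref) < 2:
        raise FeatureError(
            f"need at least 2 HC reference participants, got {len(ref)}"
        )
    mean = float(np.mean(ref))
    std = float(np.std(ref, ddof=ddof))
    if std == 0:
        raise FeatureError("HC reference similarities are all equal (std = 0)")
    return {p: (v - mean) / std for p, v in values.items()}


# ---------------------------------------------------------------------------
# Cohort-level computation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BRSResult:
    """Raw and HC-standardized similarity for one participant × region."""

    participant: str
    group: str
    region: str
    band_set: tuple[str, ...]
    raw: float
    std: float | None
    n: int
    m: int


def _series_pairs_from_epochs(
    runs: Mapping[str, tuple[EpochArray, EpochArray]],
    montage: Montage,
    bands: BandScheme,
    band_subset: Iterable[str] | None,
) -> dict[str, dict[str, tuple[RegionPowerSeries, RegionPowerSeries]]]:
    out: dict[str, dict[str, tuple[RegionPowerSeries, RegionPowerSeries]]] = {}
    subset = tuple(band_subset) if band_subset is not None else None
    for pid, pair in runs.items():
        if pair is None or len(pair) != 2 or pair[0] is None or pair[1] is None:
            raise FeatureError(f"participant {pid!r} is missing a run")
        tensors = [band_power_tensor(ep, bands) for ep in pair]
        out[pid] = {
            region: tuple(
                region_power_series(t, montage, region, subset) for t in tensors
            )
            for region in montage.region_names
        }
    return out


def brs_from_series(
    series: Mapping[str, Mapping[str, tuple[RegionPowerSeries, RegionPowerSeries]]],
    groups: Mapping[str, str],
    *,
    hc_ids: Iterable[str] | None = None,
    std_mode: str = "global",
    train_ids: Iterable[str] | None = None,
) -> list[BRSResult]:
    """Raw + standardized BRS from precomputed region power series.

    ``series`` maps participant → region → (run-1 series, run-2 series).
    ``hc_ids`` defaults to the participants labelled ``"HC"`` in ``groups``.
    """
    if not series:
        raise FeatureError("empty cohort")
    if hc_ids is None:
        hc_ids = [p for p, g in groups.items() if g == "HC"]
    hc_ids = list(hc_ids)
    first = next(iter(series.values()))
    regions = tuple(first)
    results: list[BRSResult] = []
    for region in regions:
        raw: dict[str, float] = {}
        nm: dict[str, tuple[int, int]] = {}
        for pid, per_region in series.items():
            p1, p2 = per_region[region]
            raw[pid] = between_run_similarity(p1, p2)
            nm[pid] = (p1.n_epochs, p2.n_epochs)
        std = standardize_brs(raw, hc_ids, mode=std_mode, train_ids=train_ids)
        band_set = first[region][0].band_names
        for pid in series:
            results.append(
                BRSResult(
                    participant=pid,
                    group=groups.get(pid, "unknown"),
                    region=region,
                    band_set=band_set,
                    raw=raw[pid],
                    std=std[pid],
                    n=nm[pid][0],
                    m=nm[pid][1],
                )
            )
    return results


def compute_brs_features(
    runs: Mapping[str, tuple[EpochArray, EpochArray]],
    groups: Mapping[str, str],
    montage: Montage = DEFAULT_MONTAGE,
    bands: BandScheme = DEFAULT_BANDS,
    *,
    band_subset: Iterable[str] | None = None,
    hc_ids: Iterable[str] | None = None,
    std_mode: str = "global",
    train_ids: Iterable[str] | None = None,
) -> list[BRSResult]:
    """One BRSResult per participant × montage region.

    ``runs`` maps participant id → (run-1 epochs, run-2 epochs). With the
    default six-region montage and full seven-band vectors, a cohort of N
    participants yields 6 N results.
    """
    series = _series_pairs_from_epochs(runs, montage, bands, band_subset)
    return brs_from_series(
        series, groups, hc_ids=hc_ids, std_mode=std_mode, train_ids=train_ids
    )


def brs_table(results: Sequence[BRSResult]) -> pd.DataFrame:
    """Long-format table of raw and standardized similarities."""
    rows = []
    for r in results:
        band_set = "all" if len(r.band_set) == len(DEFAULT_BANDS) else "+".join(r.band_set)
        rows.append(
            {
                "participant": r.participant,
                "group": r.group,
                "region": r.region,
                "band_set": band_set,
                "feature": "brs_raw",
                "value": r.raw,
            }
        )
        if r.std is not None:
            rows.append(
                {
                    "participant": r.participant,
                    "group": r.group,
                    "region": r.region,
                    "band_set": band_set,
                    "feature": "brs_std",
                    "value": r.std,
                }
            )
    return pd.DataFrame(rows)


def feature_matrix(
    results: Sequence[BRSResult],
    montage: Montage = DEFAULT_MONTAGE,
    *,
    value: str = "std",
) -> tuple[np.ndarray, list[str], list[str], tuple[str, ...]]:
    """Pivot BRS results to a participants × regions matrix.

    Returns ``(X, participant_ids, labels, region_names)`` with columns in
    montage region order and rows sorted by participant id.
    """
    if value not in ("std", "raw"):
        raise FeatureError("value must be 'std' or 'raw'")
    regions = montage.region_names
    by_pid: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    for r in results:
        v = r.std if value == "std" else r.raw
        if v is None:
            raise FeatureError("standardized values requested but not computed")
        by_pid.setdefault(r.participant, {})[r.region] = v
        labels[r.participant] = r.group
    pids = sorted(by_pid)
    X = np.array([[by_pid[p][reg] for reg in regions] for p in pids])
    return X, pids, [labels[p] for p in pids], regions
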