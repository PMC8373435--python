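"""Synthetic two-run EEG cohorts with controllable between-run change.

No public clinical two-run resting-state dataset accompanies this analysis,
so the generator emulates the statistical structure the between-run
similarity pipeline assumes:

* each participant owns a per-region, per-band log-normal band-power
  profile (inter-subject spread ``subject_sd`` on the natural-log scale);
* within a run, epoch-to-epoch power fluctuates log-normally around the
  profile (``epoch_jitter``);
* the run-2 profile is the run-1 profile shifted multiplicatively on power
  (additively on log power) by a group- and band-specific magnitude, with a
  random sign per participant × region × band. Larger perturbations yield
  larger between-run displacement and hence lower similarity.

Two fidelity levels are provided. ``simulate_power_vectors`` draws the
regional band-power vectors directly (fast; exercises every downstream
stage from the similarity statistic onward). ``simulate_cohort`` synthesizes
raw multichannel time series as sums of band-limited Gaussian noise whose
per-band variances follow the profiles, exercising the preprocessing and
spectral-estimation stages as well.

Determinism: a single cohort seed drives one independent substream per
participant, keyed by participant index, so adding a participant never
changes the data of the others.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
from scipy import signal

from .brs_features import RegionPowerSeries
from .config_io import (
    BandScheme,
    CohortManifest,
    DEFAULT_BANDS,
    DEFAULT_MONTAGE,
    ManifestEntry,
    Montage,
    Recording,
)
from .preprocess import design_bandpass


class SimulationError(ValueError):
    """Invalid cohort specification."""


#: Baseline band-power means in µV² (region-independent), a plausible
#: resting-state profile dominated by slow oscillations.
DEFAULT_BAND_POWER = {
    "delta": 20.0,
    "theta": 10.0,
    "low_alpha": 8.0,
    "high_alpha": 6.0,
    "low_beta": 4.0,
    "high_beta": 2.0,
    "gamma": 1.0,
}

#: Default group-specific run-2 perturbation magnitudes (log-power shift).
#: Healthy controls change little in every band; the MCI-like group shifts
#: in the fast bands (low/high beta, gamma) and the AD-like group in the
#: slow bands (delta, theta), reflecting the band-specific pattern of
#: impaired groups.
DEFAULT_PERTURBATION: dict[str, dict[str, float]] = {
    "HC": {b: 0.05 for b in DEFAULT_BAND_POWER},
    "MCI": {
        **{b: 0.05 for b in DEFAULT_BAND_POWER},
        "low_beta": 0.5, "high_beta": 0.5, "gamma": 0.5,
    },
    "AD": {
        **{b: 0.05 for b in DEFAULT_BAND_POWER},
        "delta": 0.5, "theta": 0.5,
    },
}


def _expand_perturbation(
    perturbation: Mapping[str, Mapping[str, float] | float] | None,
    band_names: tuple[str, ...],
    group_names: tuple[str, ...],
) -> dict[str, dict[str, float]]:
    if perturbation is None:
        perturbation = DEFAULT_PERTURBATION
    out: dict[str, dict[str, float]] = {}
    for g in group_names:
        spec = perturbation.get(g, 0.0)
        if isinstance(spec, Mapping):
            out[g] = {b: float(spec.get(b, 0.0)) for b in band_names}
        else:
            out[g] = {b: float(spec) for b in band_names}
        if min(out[g].values()) < 0:
            raise SimulationError(f"perturbation magnitudes must be >= 0 ({g})")
    return out


@dataclasses.dataclass
class CohortSpec:
    """Conditions of a simulated two-run cohort.

    Defaults mirror the study conditions of the reference cohort: group
    sizes 27 HC / 24 MCI / 23 AD, 90 s runs at 500 Hz, log-normal band
    powers with inter-subject spread 0.4 and epoch jitter 0.15 (natural-log
    scale), and small HC vs band-specific patient run-2 perturbations.
    """

    group_sizes: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"HC": 27, "MCI": 24, "AD": 23}
    )
    band_power_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BAND_POWER)
    )
    subject_sd: float = 0.4
    epoch_jitter: float = 0.15
    perturbation: Mapping[str, Mapping[str, float] | float] | None = None
    rate_hz: float = 500.0
    duration_s: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise SimulationError("group sizes must be >= 0")
        if self.subject_sd < 0 or self.epoch_jitter < 0:
            raise SimulationError("spread and jitter scales must be >= 0")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise SimulationError("rate and duration must be positive")
        if min(self.band_power_mean.values()) <= 0:
            raise SimulationError("baseline band powers must be positive")

    def participants(self) -> list[tuple[str, str, int]]:
        """(participant id, group, global index) in a fixed order."""
        out = []
        idx = 0
        for group, count in self.group_sizes.items():
            for k in range(count):
                out.append((f"{group}{k + 1:02d}", group, idx))
                idx += 1
        return out


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _band_means(spec: CohortSpec, bands: BandScheme) -> np.ndarray:
    try:
        return np.array([float(spec.band_power_mean[b]) for b in bands.names])
    except KeyError as exc:
        raise SimulationError(f"band_power_mean missing band {exc}") from None


def _subject_profiles(
    spec: CohortSpec,
    group: str,
    montage: Montage,
    bands: BandScheme,
    pert: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-region (run-1, run-2) band-power profiles for one participant."""
    means = _band_means(spec, bands)
    pvec = np.array([pert[b] for b in bands.names])
    out = {}
    for region in montage.region_names:
        p1 = means * np.exp(spec.subject_sd * rng.standard_normal(len(bands)))
        sign = rng.choice([-1.0, 1.0], size=len(bands))
        p2 = p1 * np.exp(sign * pvec)
        out[region] = (p1, p2)
    return out


# ---------------------------------------------------------------------------
# Power-vector level
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PowerCohort:
    """Power-vector-level cohort: participant → region → run series pair."""

    groups: dict[str, str]
    series: dict[str, dict[str, tuple[RegionPowerSeries, RegionPowerSeries]]]

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.series)


def simulate_power_vectors(
    spec: CohortSpec,
    n_epochs: int = 36,
    montage: Montage = DEFAULT_MONTAGE,
    bands: BandScheme = DEFAULT_BANDS,
) -> PowerCohort:
    """Draw regional band-power vectors directly (fast fidelity level).

    Each run yields ``n_epochs`` vectors per region; epoch fluctuation is
    log-normal around the subject's run profile. Deterministic given
    ``spec.seed``.
    """
    if n_epochs < 1:
        raise SimulationError(f"n_epochs must be >= 1, got {n_epochs}")
    pert = _expand_perturbation(
        spec.perturbation, bands.names, tuple(spec.group_sizes)
    )
    groups: dict[str, str] = {}
    series: dict[str, dict[str, tuple[RegionPowerSeries, RegionPowerSeries]]] = {}
    for pid, group, idx in spec.participants():
        rng = _participant_rng(spec.seed, idx)
        profiles = _subject_profiles(spec, group, montage, bands, pert[group], rng)
        per_region = {}
        for region, (p1, p2) in profiles.items():
            runs = []
            for run, profile in ((1, p1), (2, p2)):
                z = rng.standard_normal((n_epochs, len(bands)))
                vectors = profile * np.exp(spec.epoch_jitter * z)
                runs.append(
                    RegionPowerSeries(
                        participant=pid,
                        run=run,
                        region=region,
                        band_names=bands.names,
                        vectors=vectors,
                    )
                )
            per_region[region] = tuple(runs)
        series[pid] = per_region
        groups[pid] = group
    return PowerCohort(groups=groups, series=series)


# ---------------------------------------------------------------------------
# Signal level
# ---------------------------------------------------------------------------

def _band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    rate: float,
    low: float,
    high: float,
    target_power: float,
) -> np.ndarray:
    """White Gaussian noise band-passed to [low, high] and rescaled so its
    sample variance equals ``target_power``."""
    taps = design_bandpass(low, high, rate)
    white = rng.standard_normal(n_samples)
    padlen = min(3 * len(taps), n_samples - 1)
    comp = signal.filtfilt(taps, [1.0], white, padlen=padlen)
    sd = comp.std()
    if sd == 0:
        return comp
    return comp * (np.sqrt(target_power) / sd)


def simulate_cohort(
    spec: CohortSpec,
    montage: Montage = DEFAULT_MONTAGE,
    bands: BandScheme = DEFAULT_BANDS,
    *,
    epoch_s: float = 6.0,
) -> tuple[list[tuple[Recording, Recording]], CohortManifest]:
    """Synthesize raw two-run recordings for every participant.

    Each channel is a sum of band-limited Gaussian noise components whose
    variances follow the participant's per-region run profile; run 2 uses
    the perturbed profile. ``epoch_s`` is only checked against the run
    duration so that at least one downstream epoch fits.
    """
    if spec.duration_s < epoch_s:
        raise SimulationError(
            f"run duration {spec.duration_s} s is shorter than one "
            f"{epoch_s} s epoch"
        )
    pert = _expand_perturbation(
        spec.perturbation, bands.names, tuple(spec.group_sizes)
    )
    n_samples = int(round(spec.duration_s * spec.rate_hz))
    # channel -> region lookup in montage order (first region wins for
    # electrodes shared between regions)
    channel_region: dict[str, str] = {}
    for region in montage.region_names:
        for e in montage.electrodes(region):
            channel_region.setdefault(e, region)
    channels = tuple(channel_region)

    pairs: list[tuple[Recording, Recording]] = []
    entries: dict[str, ManifestEntry] = {}
    for pid, group, idx in spec.participants():
        rng = _participant_rng(spec.seed, idx)
        profiles = _subject_profiles(spec, group, montage, bands, pert[group], rng)
        recs = []
        for run in (1, 2):
            data = np.zeros((len(channels), n_samples))
            for c, name in enumerate(channels):
                profile = profiles[channel_region[name]][run - 1]
                for band, power in zip(bands, profile):
                    data[c] += _band_limited_noise(
                        rng, n_samples, spec.rate_hz, band.low, band.high, power
                    )
            recs.append(
                Recording(
                    participant=pid,
                    group=group,
                    run=run,
                    samples=data,
                    rate=spec.rate_hz,
                    channels=channels,
                )
            )
        pairs.append((recs[0], recs[1]))
        entries[pid] = ManifestEntry(
            group=group, run1=f"memory://{pid}/run1", run2=f"memory://{pid}/run2"
        )
    return pairs, CohortManifest(entries)


def inject_spike(
    rec: Recording, channel: str, time_s: float, amplitude_uv: float
) -> Recording:
    """Return a copy of ``rec`` with a single-sample spike added, for
    exercising the amplitude-based epoch rejector."""
    idx = rec.channel_index(channel)
    t = int(round(time_s * rec.rate))
    if not (0 <= t < rec.n_samples):
        raise SimulationError(f"spike time {time_s} s outside the recording")
    samples = rec.samples.copy()
    samples[idx, t] += amplitude_uv
    return Recording(
        participant=rec.participant,
        group=rec.group,
        run=rec.run,
        samples=samples,
        rate=rec.rate,
        channels=rec.channels,
    )
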