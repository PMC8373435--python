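"""Montage and band configuration, recording ingestion, tabular result I/O.

Everything downstream (preprocessing, band powers, between-run similarity,
classification, statistics) is parameterised by two small configuration
objects defined here:

* :class:`BandScheme` — the ordered list of spectral bands. The default is
  the seven-band clinical scheme (delta through gamma, 1–45 Hz); the band
  order fixes the component order of every power vector in the package.
* :class:`Montage` — named scalp regions, each an ordered list of 10–20
  electrode names. The default is the six-region, 30-electrode layout used
  for regional averaging (frontal, central, parietal, occipital, left and
  right temporal).

Recordings are either EDF files (read through :mod:`mne`, installed via the
``edf`` extra) or the package's own plain-text array format: a numeric
channels × samples matrix (``.csv`` or ``.npy``) with a YAML sidecar holding
``rate_hz``, ``channels`` and ``units``. All samples are held in microvolts.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class ConfigurationError(ValueError):
    """Invalid montage/band configuration."""


class IngestionError(ValueError):
    """A recording file could not be ingested."""


GROUP_LABELS = ("HC", "MCI", "AD", "unknown")

#: Fixed column set for feature/result tables.
TABLE_COLUMNS = ("participant", "group", "region", "band_set", "feature", "value")


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Band:
    """A named frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 <= low < high, got ({self.low}, {self.high})"
            )


_DEFAULT_BANDS = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("low_alpha", 8.0, 10.0),
    Band("high_alpha", 10.0, 13.0),
    Band("low_beta", 13.0, 20.0),
    Band("high_beta", 20.0, 30.0),
    Band("gamma", 30.0, 45.0),
)


class BandScheme:
    """Ordered, named frequency bands.

    The order of the bands defines the component order of every band-power
    vector produced by the package.
    """

    def __init__(self, bands: Iterable[Band]):
        bands = tuple(bands)
        if not bands:
            raise ConfigurationError("band scheme must contain at least one band")
        names = [b.name for b in bands]
        if len(set(names)) != len(names):
            raise ConfigurationError("band names must be unique")
        self.bands = bands

    @classmethod
    def default(cls) -> "BandScheme":
        """The seven-band clinical scheme: delta 1–4, theta 4–8, low alpha
        8–10, high alpha 10–13, low beta 13–20, high beta 20–30, gamma
        30–45 Hz."""
        return cls(_DEFAULT_BANDS)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown band {name!r}; have {self.names}") from None

    def __getitem__(self, name: str) -> Band:
        return self.bands[self.index(name)]

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        spans = ", ".join(f"{b.name} {b.low:g}-{b.high:g}" for b in self.bands)
        return f"BandScheme({spans})"


DEFAULT_BANDS = BandScheme.default()


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def _default_regions(occipital_third: str = "Oz") -> dict[str, tuple[str, ...]]:
    if occipital_third not in ("Oz", "Cz"):
        raise ConfigurationError("occipital_third must be 'Oz' or 'Cz'")
    return {
        "frontal": ("FP1", "FP2", "F3", "F4", "F7", "F8", "Fz"),
        "central": ("FC3", "FC4", "FCz", "C3", "C4", "Cz"),
        "parietal": ("CP3", "CP4", "CPz", "P3", "P4", "Pz"),
        "occipital": ("O1", "O2", occipital_third),
        "left_temporal": ("FT7", "T3", "TP7", "T5"),
        "right_temporal": ("FT8", "T4", "TP8", "T6"),
    }


@dataclasses.dataclass(frozen=True)
class Montage:
    """Named scalp regions, each an ordered electrode-name list.

    Region order is meaningful: it defines the deterministic ordering of
    per-region results and the tie-break order in feature selection.
    """

    regions: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ConfigurationError("montage must define at least one region")
        clean: dict[str, tuple[str, ...]] = {}
        for name, electrodes in self.regions.items():
            electrodes = tuple(electrodes)
            if not electrodes:
                raise ConfigurationError(f"region {name!r} is empty")
            if len(set(electrodes)) != len(electrodes):
                dups = sorted({e for e in electrodes if electrodes.count(e) > 1})
                raise ConfigurationError(
                    f"region {name!r} lists electrodes more than once: {dups}"
                )
            clean[name] = electrodes
        object.__setattr__(self, "regions", clean)

    @classmethod
    def default(cls, occipital_third: str = "Oz") -> "Montage":
        """Six-region, 30-electrode default layout.

        ``occipital_third`` selects the third occipital electrode: ``"Oz"``
        (default, giving 30 unique electrodes) or ``"Cz"`` (which duplicates
        the central electrode of the same name across regions).
        """
        return cls(_default_regions(occipital_third))

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def n_e(self, region: str) -> int:
        """Number of electrodes in ``region``."""
        return len(self.electrodes(region))

    def electrodes(self, region: str) -> tuple[str, ...]:
        try:
            return self.regions[region]
        except KeyError:
            raise KeyError(
                f"unknown region {region!r}; have {self.region_names}"
            ) from None

    @property
    def all_electrodes(self) -> tuple[str, ...]:
        """All electrodes in region order, duplicates removed (first wins)."""
        seen: dict[str, None] = {}
        for electrodes in self.regions.values():
            for e in electrodes:
                seen.setdefault(e, None)
        return tuple(seen)


DEFAULT_MONTAGE = Montage.default()


def load_montage(path: str | Path | None = None, *, occipital_third: str = "Oz") -> Montage:
    """Load a montage from a YAML file, or return the built-in default.

    The YAML layout is ``{regions: {region_name: [electrode, ...], ...}}``.
    ``path=None`` or a non-existent path returns :meth:`Montage.default`.
    """
    if path is None:
        return Montage.default(occipital_third)
    path = Path(path)
    if not path.exists():
        return Montage.default(occipital_third)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "regions" not in doc:
        raise ConfigurationError(f"{path}: expected a mapping with a 'regions' key")
    regions = doc["regions"]
    if not isinstance(regions, Mapping) or not regions:
        raise ConfigurationError(f"{path}: 'regions' must be a non-empty mapping")
    return Montage({str(k): tuple(v or ()) for k, v in regions.items()})


def save_montage(montage: Montage, path: str | Path) -> None:
    doc = {"regions": {k: list(v) for k, v in montage.regions.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Recording:
    """One participant-run of multichannel EEG.

    ``samples`` is an electrodes × time matrix in microvolts; ``channels``
    names its rows in order.
    """

    participant: str
    group: str
    run: int
    samples: np.ndarray
    rate: float
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise IngestionError("samples must be a 2-D electrodes x time matrix")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.samples.shape[0]:
            raise IngestionError(
                f"{len(self.channels)} channel names for "
                f"{self.samples.shape[0]} sample rows"
            )
        if not self.rate > 0:
            raise IngestionError(f"sampling rate must be positive, got {self.rate}")
        if self.run not in (1, 2):
            raise IngestionError(f"run index must be 1 or 2, got {self.run}")
        if self.group not in GROUP_LABELS:
            raise IngestionError(
                f"group must be one of {GROUP_LABELS}, got {self.group!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


_UNIT_SCALE = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def read_recording(
    path: str | Path,
    *,
    participant: str = "",
    group: str = "unknown",
    run: int = 1,
    montage: Montage | None = None,
) -> Recording:
    """Read a recording from EDF or the package array format.

    The array format is a channels × samples matrix (``.csv`` comma-separated
    or ``.npy``) with a YAML sidecar ``<stem>.yaml`` holding ``rate_hz``,
    ``channels`` and optionally ``units`` (default microvolts). If ``montage``
    is given, every montage electrode must be present among the channels.
    """
    path = Path(path)
    if not path.exists():
        raise IngestionError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        samples, rate, channels = _read_edf(path)
    else:
        samples, rate, channels = _read_array(path)
    rec = Recording(
        participant=participant or path.stem,
        group=group,
        run=run,
        samples=samples,
        rate=rate,
        channels=channels,
    )
    if montage is not None:
        missing = [e for e in montage.all_electrodes if e not in rec.channels]
        if missing:
            raise IngestionError(
                f"{path}: {len(missing)} montage channel(s) missing: "
                + ", ".join(missing)
            )
    return rec


def _read_edf(path: Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise IngestionError(
            "reading EDF requires the 'mne' package (install brs-eeg[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne returns volts
    return samples, float(raw.info["sfreq"]), tuple(raw.ch_names)


def _read_array(path: Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise IngestionError(f"sidecar not found for {path}: expected {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    try:
        rate = float(meta["rate_hz"])
    except (KeyError, TypeError, ValueError):
        raise IngestionError(f"{sidecar}: unreadable or missing 'rate_hz'") from None
    channels = tuple(str(c) for c in meta.get("channels", ()))
    if not channels:
        raise IngestionError(f"{sidecar}: missing 'channels' list")
    units = str(meta.get("units", "uV"))
    if units not in _UNIT_SCALE:
        raise IngestionError(f"{sidecar}: unknown units {units!r}")
    if path.suffix.lower() == ".npy":
        samples = np.load(path)
    else:
        samples = np.loadtxt(path, delimiter=",", ndmin=2)
    return samples * _UNIT_SCALE[units], rate, channels


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the package array format (matrix + YAML sidecar).

    ``.csv`` matrices use 17 significant digits so float64 samples round-trip
    bit-identically; ``.npy`` is lossless by construction.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".npy":
        np.save(path, rec.samples)
    else:
        np.savetxt(path, rec.samples, delimiter=",", fmt="%.17g")
    meta = {
        "rate_hz": float(rec.rate),
        "channels": list(rec.channels),
        "units": "uV",
        "participant": rec.participant,
        "group": rec.group,
        "run": int(rec.run),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ManifestEntry:
    group: str
    run1: str
    run2: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ConfigurationError(
                f"group must be one of {GROUP_LABELS}, got {self.group!r}"
            )


@dataclasses.dataclass(frozen=True)
class CohortManifest:
    """Participant id → (group label, run-1 source, run-2 source)."""

    entries: Mapping[str, ManifestEntry]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def group_of(self, participant: str) -> str:
        return self.entries[participant].group

    @property
    def groups(self) -> dict[str, str]:
        return {p: e.group for p, e in self.entries.items()}


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"participant": p, "group": e.group, "run1": e.run1, "run2": e.run2}
        for p, e in manifest.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, dtype=str)
    required = {"participant", "group", "run1", "run2"}
    if not required.issubset(df.columns):
        raise IngestionError(f"{path}: manifest needs columns {sorted(required)}")
    entries = {
        str(r.participant): ManifestEntry(str(r.group), str(r.run1), str(r.run2))
        for r in df.itertuples()
    }
    return CohortManifest(entries)


# ---------------------------------------------------------------------------
# Feature / result tables
# ---------------------------------------------------------------------------

def write_table(
    records: Sequence[Mapping],
    path: str | Path,
    fmt: str = "csv",
    *,
    region_order: Sequence[str] | None = None,
) -> Path:
    """Write feature/result records with the fixed column set.

    One row per participant × region × feature; rows are ordered by
    participant id, then region (in ``region_order`` if given, else the
    default montage's region order, unknown regions last), then feature.
    Values are written with 15 significant digits.
    """
    if not records:
        raise ValueError("refusing to write an empty table")
    rows = [dict(r) for r in records]
    for r in rows:
        missing = [c for c in TABLE_COLUMNS if c not in r]
        if missing:
            raise ValueError(f"record missing columns {missing}: {r}")
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    order = tuple(region_order) if region_order else DEFAULT_MONTAGE.region_names
    rank = {name: i for i, name in enumerate(order)}
    df["_r"] = df["region"].map(lambda x: rank.get(x, len(rank)))
    df = df.sort_values(["participant", "_r", "feature"], kind="stable")
    df = df.drop(columns="_r").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.15g")
    elif fmt == "json":
        df.to_json(path, orient="records", double_precision=15, indent=1)
    else:
        raise ValueError(f"unknown table format {fmt!r} (use 'csv' or 'json')")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path, orient="records")
    else:
        df = pd.read_csv(path)
    return df
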