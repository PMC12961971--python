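"""Shared domain containers and errors.

The containers mirror the data streams of a responsive-neurostimulation
(RNS-class) implant: hourly detection counts (dIEA), an event catalog of
Long Episodes (LE, seizure surrogates) and Scheduled Events (SE, twice-daily
90-s baseline EEG clips), and 4-channel EEG clips (two bipolar channels per
electrode lead, two leads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class MultidienError(Exception):
    """Base class for package errors."""


class ConfigurationError(MultidienError):
    """Invalid simulation or pipeline configuration."""


class InsufficientDataError(MultidienError):
    """Not enough data survives preprocessing / inclusion rules."""


class NoMultidienCycleError(MultidienError):
    """No significant multidien periodogram peak (exclusion criterion)."""


class DegenerateContrastError(MultidienError):
    """A classification contrast has an absent or too-small class."""


class ClipRejectedError(MultidienError):
    """An EEG clip failed quality control (e.g. amplifier saturation)."""


BIN_LABELS = ("peak", "falling", "trough", "rising")

#: Canonical frequency bands (Hz). The gamma band is capped at 100 Hz, the
#: effective bandwidth of 250-Hz device recordings.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (33.0, 100.0),
}

POWER_FEATURES = tuple(f"{b}_power" for b in BANDS)
XWT_FEATURES = tuple(f"{b}_xwt" for b in BANDS)
EEG_FEATURES = POWER_FEATURES + XWT_FEATURES
ALL_FEATURES = EEG_FEATURES + ("tod", "spike_rate")


@dataclass
class DIEASeries:
    """Hourly device-detected interictal epileptiform activity counts.

    After :func:`multidien.cycles.preprocess_diea` the arrays cover only the
    retained analysis segments on a uniform hourly grid (segments may be
    separated by discarded gaps), ``interp_mask`` flags interpolated samples
    and ``z`` holds counts z-scored within clinic-visit intervals.
    """

    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    visit_dates: pd.DatetimeIndex
    interp_mask: np.ndarray | None = None
    z: np.ndarray | None = None
    segment_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("dIEA counts must be non-negative")
        if self.interp_mask is None:
            self.interp_mask = np.zeros(len(self.counts), bool)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def interp_fraction(self) -> float:
        return float(np.mean(self.interp_mask))

    def segments(self) -> Iterator[tuple[int, slice]]:
        """Yield ``(segment_id, slice)`` for each contiguous analysis segment."""
        if self.segment_ids is None:
            yield 0, slice(0, len(self))
            return
        ids = np.asarray(self.segment_ids)
        for sid in np.unique(ids):
            idx = np.flatnonzero(ids == sid)
            yield int(sid), slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class EventCatalog:
    """Catalog of device recordings: LE (seizure surrogate) and SE entries.

    ``frame`` columns: ``event_id, timestamp, type`` (``"LE"``/``"SE"``),
    ``has_stim`` (bool), ``stim_offsets_s`` (list of seconds into the clip).
    """

    frame: pd.DataFrame

    REQUIRED = ("event_id", "timestamp", "type", "has_stim", "stim_offsets_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"event catalog missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def ses(self, *, stim: bool | None = None) -> pd.DataFrame:
        df = self.frame[self.frame["type"] == "SE"]
        if stim is not None:
            df = df[df["has_stim"] == stim]
        return df

    def les(self) -> pd.DataFrame:
        return self.frame[self.frame["type"] == "LE"]

    @property
    def le_times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.les()["timestamp"])


@dataclass
class EEGClip:
    """A 4-channel EEG clip (µV); two bipolar channels per lead."""

    samples: np.ndarray  # (4, n) float, µV
    fs: float
    timestamp: pd.Timestamp
    clip_type: str = "SE"
    stim_offsets_s: Sequence[float] = field(default_factory=list)
    channel_lead_map: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"lead1": (0, 1), "lead2": (2, 3)}
    )
    detection_channels: tuple[int, int] = (0, 2)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 4:
            raise ValueError(
                f"expected 4 channels, got shape {self.samples.shape}"
            )
        if not all(0 <= c < 4 for c in self.detection_channels):
            raise ValueError("detection channels must index into 0..3")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def window(self, start_s: float, end_s: float) -> "EEGClip":
        """Return the sub-clip covering ``[start_s, end_s)`` seconds."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError("window outside clip")
        return EEGClip(
            self.samples[:, i0:i1],
            self.fs,
            self.timestamp + pd.Timedelta(seconds=start_s),
            self.clip_type,
            [o - start_s for o in self.stim_offsets_s if start_s <= o < end_s],
            self.channel_lead_map,
            self.detection_channels,
        )


@dataclass
class Periodogram:
    """Time-averaged wavelet power over a log-spaced multidien period grid."""

    periods_days: np.ndarray
    power: np.ndarray
    n_avg: np.ndarray  # samples averaged per period (COI-excluded)
    rednoise_threshold: np.ndarray | None = None
    ar1_coef: float = float("nan")
    peaks: list[tuple[float, float]] = field(default_factory=list)
    variance: float = 1.0
    omega0: float = 6.0

    def significant(self) -> np.ndarray:
        if self.rednoise_threshold is None:
            raise ValueError("red-noise threshold not computed yet")
        return self.power > self.rednoise_threshold


@dataclass
class CycleComponent:
    """A band-reconstructed multidien oscillation with instantaneous phase."""

    period_days: float
    timestamps: pd.DatetimeIndex
    signal: np.ndarray
    phase: np.ndarray  # radians in (-pi, pi]
    segment_ids: np.ndarray | None = None
    plv: float = float("nan")
    le_phases: np.ndarray | None = None

    def phase_at(self, times, max_gap_hours: float = 1.0) -> np.ndarray:
        """Phase at the nearest hourly sample; NaN outside analysis segments."""
        times = pd.DatetimeIndex(times)
        idx = self.timestamps.get_indexer(times, method="nearest")
        gap = np.abs(
            (times - self.timestamps[idx]).total_seconds()
        ) / 3600.0
        out = self.phase[idx].astype(float).copy()
        out[gap > max_gap_hours] = np.nan
        return out


@dataclass
class ClassifierReport:
    """Cross-validated phase-classification outcome for one contrast."""

    contrast: str
    feature_set: str
    fold_aucs: np.ndarray
    mean_auc: float
    n_rows: int
    class_counts: dict[str, int]
    coefficients: pd.Series | None = None
    null_aucs: np.ndarray | None = None
    p_value: float = float("nan")


@dataclass
class EffectSizeRecord:
    """Peak-vs-trough or rising-vs-falling effect size for one feature."""

    patient_id: str
    feature: str
    contrast: str  # "PvT" or "RvF"
    cohens_d: float
    n1: int
    n2: int
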