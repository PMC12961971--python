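"""Per-clip EEG features: spike rate, band power, cross-wavelet connectivity.

Each analysis window (a full stimulation-free 90-s Scheduled Event, or a
10-s window starting 2 s after a stimulation) yields one feature row:
theta/alpha/beta/gamma band power (Welch, max over the two detection
channels, log10), theta/alpha/beta/gamma cross-wavelet connectivity
(within-lead, max over leads), a day/night covariate, and spike rate per
90-s equivalent.  Features are z-scored within clinic-visit segments to
absorb detection-parameter changes and slow drifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, peak_widths, sosfiltfilt, welch

from . import wavelet
from .types import (
    ALL_FEATURES,
    BANDS,
    ClipRejectedError,
    CycleComponent,
    EEGClip,
    EventCatalog,
    InsufficientDataError,
    POWER_FEATURES,
)
from .cycles import assign_phase_bin

logger = logging.getLogger(__name__)

#: Mains frequency notch excluded from the gamma band (Hz).
MAINS_EXCLUSION = (58.0, 62.0)


@dataclass
class SpikeDetectorParams:
    """Thresholds of the morphology-gated robust-amplitude spike detector."""

    band_hz: tuple[float, float] = (1.0, 35.0)
    threshold_z: float = 6.0
    sharpness_z: float = 2.0
    #: accepted event duration (ms), measured near the lobe base (at 10% of
    #: peak prominence) to match the clinical total-duration convention
    width_ms: tuple[float, float] = (20.0, 200.0)
    width_rel_height: float = 0.9
    merge_ms: float = 200.0
    stim_mask_pad_s: float = 1.0
    saturation_fraction: float = 0.2


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = x.std() or 1.0
    return (x - med) / scale


def detect_spikes(
    clip: EEGClip, params: SpikeDetectorParams | None = None
) -> np.ndarray:
    """Merged interictal-spike event times (seconds into the clip).

    Per channel: band-pass 1-35 Hz, robust z (median/MAD); candidates are
    local extrema with |z| above threshold whose event duration (width near
    the lobe base) lies in 20-200 ms and whose second-difference sharpness
    exceeds its own robust-z threshold.  Samples within ``stim_mask_pad_s`` of a
    stimulation offset are masked first; events within 200 ms across
    channels are merged.  Clips with >20% of samples at the amplifier rail
    are rejected.
    """
    p = params or SpikeDetectorParams()
    fs = clip.fs
    if clip.n_samples < fs:
        raise ValueError("clip shorter than 1 s")
    rail = np.abs(clip.samples).max(axis=1, keepdims=True)
    if np.all(rail > 0):
        at_rail = np.mean(
            np.abs(clip.samples) >= rail * (1 - 1e-9), axis=1
        )
        if np.any(at_rail > p.saturation_fraction):
            raise ClipRejectedError(
                f"saturated clip: {at_rail.max():.0%} of samples at rail"
            )
    mask = np.zeros(clip.n_samples, bool)
    for off in clip.stim_offsets_s:
        i0 = int((off - p.stim_mask_pad_s) * fs)
        i1 = int((off + p.stim_mask_pad_s + 0.1) * fs)
        mask[max(i0, 0): min(i1, clip.n_samples)] = True
    sos = butter(4, p.band_hz, btype="bandpass", fs=fs, output="sos")
    all_times: list[float] = []
    min_w = p.width_ms[0] * fs / 1000.0
    max_w = p.width_ms[1] * fs / 1000.0
    for ch in range(4):
        x = sosfiltfilt(sos, clip.samples[ch])
        z = _robust_z(x)
        az = np.abs(z)
        az[mask] = 0.0
        peaks, _ = find_peaks(az, height=p.threshold_z)
        if peaks.size == 0:
            continue
        widths = peak_widths(az, peaks, rel_height=p.width_rel_height)[0]
        d2 = np.zeros_like(z)
        d2[1:-1] = np.abs(np.diff(z, 2))
        sharp = _robust_z(d2)
        for pk, w in zip(peaks, widths):
            if min_w <= w <= max_w and sharp[pk] > p.sharpness_z:
                all_times.append(pk / fs)
    if not all_times:
        return np.array([])
    all_times.sort()
    merged = [all_times[0]]
    for t in all_times[1:]:
        if t - merged[-1] > p.merge_ms / 1000.0:
            merged.append(t)
    return np.asarray(merged)


def spike_rate(
    spike_times, duration_s: float, per_s: float = 90.0
) -> float:
    """Spike count scaled to events per ``per_s`` seconds (90-s clip
    equivalent)."""
    if duration_s <= 0:
        raise ValueError("zero analyzed duration")
    return len(np.atleast_1d(spike_times)) * per_s / duration_s


def _check_band(band: str | tuple[float, float], fs: float):
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if hi > fs / 2.0:
        raise ValueError(f"band ({lo}-{hi} Hz) exceeds Nyquist ({fs / 2} Hz)")
    return lo, hi


def band_power(
    clip: EEGClip,
    band: str | tuple[float, float],
    window_s: tuple[float, float] | None = None,
) -> float:
    """Welch band power, max over the two detection channels.

    1-s Hamming windows with 50% overlap; mean power density over the band
    frequencies; 60 +- 2 Hz excluded from the gamma band (mains artifact).
    Returned on the raw (not log) scale.
    """
    lo, hi = _check_band(band, clip.fs)
    sub = clip if window_s is None else clip.window(*window_s)
    if sub.duration_s < 2.0:
        raise ValueError("band power needs a window of at least 2 s")
    nperseg = int(sub.fs)
    best = 0.0
    for ch in clip.detection_channels:
        f, pxx = welch(
            sub.samples[ch],
            fs=sub.fs,
            window="hamming",
            nperseg=nperseg,
            noverlap=nperseg // 2,
        )
        sel = (f >= lo) & (f < hi)
        if band == "gamma" or (lo, hi) == BANDS["gamma"]:
            sel &= ~((f >= MAINS_EXCLUSION[0]) & (f <= MAINS_EXCLUSION[1]))
        best = max(best, float(pxx[sel].mean()) if sel.any() else 0.0)
    return best


def _band_periods(lo: float, hi: float, voices: int = 6) -> np.ndarray:
    return wavelet.period_grid(1.0 / hi, 1.0 / lo, voices)


def _xwt_lead_value(Wa, Wb, fs: float, n: int) -> float:
    """Mean over 1-s non-overlapping windows of the normalised cross-wavelet
    magnitude between two channels of one lead."""
    step = int(fs)
    nwin = n // step
    if nwin < 1:
        raise ValueError("connectivity needs at least one full 1-s window")
    nsc = Wa.shape[0]
    a = Wa[:, : nwin * step].reshape(nsc, nwin, step)
    b = Wb[:, : nwin * step].reshape(nsc, nwin, step)
    cross = np.abs((a * np.conj(b)).sum(axis=(0, 2)))
    norm = np.sqrt(
        (np.abs(a) ** 2).sum(axis=(0, 2)) * (np.abs(b) ** 2).sum(axis=(0, 2))
    )
    vals = np.where(norm > 0, cross / np.maximum(norm, 1e-300), 0.0)
    return float(vals.mean())


def _cwt_pad(periods: np.ndarray, fs: float) -> int:
    # pad ~16x the longest wavelet period: ample for edge decay at EEG scales
    return int(np.ceil(16.0 * float(np.max(periods)) * fs))


def xwt_connectivity(
    clip: EEGClip,
    band: str | tuple[float, float],
    window_s: tuple[float, float] | None = None,
    voices: int = 6,
) -> float:
    """Normalised cross-wavelet connectivity within leads, max over leads.

    Within each lead the complex Morlet CWTs of the two channels are
    combined per 1-s non-overlapping window as
    ``|sum W_a conj(W_b)| / sqrt(sum |W_a|^2 sum |W_b|^2)`` over samples x
    scales; the lead value is the window mean.  Bounded in [0, 1]; equals 1
    for identical signals.
    """
    lo, hi = _check_band(band, clip.fs)
    sub = clip if window_s is None else clip.window(*window_s)
    periods = _band_periods(lo, hi, voices)
    best = 0.0
    for lead, (c1, c2) in clip.channel_lead_map.items():
        W, _ = wavelet.morlet_cwt(
            sub.samples[[c1, c2]],
            1.0 / sub.fs,
            periods,
            pad_samples=_cwt_pad(periods, sub.fs),
        )
        best = max(best, _xwt_lead_value(W[0], W[1], sub.fs, sub.n_samples))
    return best


def extract_post_stim_windows(
    clip: EEGClip, guard_s: float = 2.0, length_s: float = 10.0
) -> list[tuple[float, float]]:
    """Post-stimulation analysis windows ``[t + guard, t + guard + length]``.

    A window is discarded if it extends past the clip end or contains a
    later stimulation's artifact; windows are returned in time order.
    """
    windows = []
    offs = sorted(clip.stim_offsets_s)
    for i, t in enumerate(offs):
        start, end = t + guard_s, t + guard_s + length_s
        if end > clip.duration_s:
            continue
        if any(start < o < end for o in offs if o != t):
            continue
        windows.append((start, end))
    return windows


def time_of_day(timestamp) -> int:
    """Day/night covariate: 1 for local time in [08:00, 20:00), else 0."""
    ts = pd.Timestamp(timestamp)
    return int(8 <= ts.hour < 20)


def zscore_by_segment(
    table: pd.DataFrame,
    feature_cols=None,
    segment_col: str = "segment_id",
    min_rows: int = 10,
) -> pd.DataFrame:
    """Z-score features within clinic-visit segments.

    Zero-variance features map to 0; the binary ``tod`` covariate is left
    untouched.  Segments with fewer than ``min_rows`` rows are flagged via
    ``segment_ok=False`` (excluded from modeling by callers).
    """
    cols = list(feature_cols) if feature_cols is not None else [
        c for c in ALL_FEATURES if c != "tod" and c in table.columns
    ]
    out = table.copy()
    out["segment_ok"] = True
    for _, idx in out.groupby(segment_col).groups.items():
        block = out.loc[idx, cols]
        sd = block.std(ddof=0)
        z = (block - block.mean()) / sd.replace(0.0, np.inf)
        out.loc[idx, cols] = z.fillna(0.0)
        if len(idx) < min_rows:
            out.loc[idx, "segment_ok"] = False
    return out


def compute_feature_row(
    clip: EEGClip,
    window_s: tuple[float, float] | None = None,
    detector_params: SpikeDetectorParams | None = None,
    spike_times: np.ndarray | None = None,
    xwt_voices: int = 6,
) -> dict[str, float]:
    """All raw features of one analysis window (single CWT pass per lead)."""
    sub = clip if window_s is None else clip.window(*window_s)
    if sub.duration_s < 2.0:
        raise ValueError("feature window must be at least 2 s")
    row: dict[str, float] = {}
    # one Welch pass per detection channel covers all four power bands
    nperseg = int(sub.fs)
    psds = [
        welch(
            sub.samples[ch],
            fs=sub.fs,
            window="hamming",
            nperseg=nperseg,
            noverlap=nperseg // 2,
        )
        for ch in clip.detection_channels
    ]
    for band, (lo, hi) in BANDS.items():
        _check_band(band, clip.fs)
        vals = []
        for f, pxx in psds:
            sel = (f >= lo) & (f < hi)
            if band == "gamma":
                sel &= ~(
                    (f >= MAINS_EXCLUSION[0]) & (f <= MAINS_EXCLUSION[1])
                )
            vals.append(float(pxx[sel].mean()) if sel.any() else 0.0)
        row[f"{band}_power"] = max(vals)
    # one CWT per lead covering every band, then split by scale range
    grids = {b: _band_periods(*BANDS[b], xwt_voices) for b in BANDS}
    all_periods = np.concatenate([grids[b] for b in BANDS])
    splits = np.cumsum([len(grids[b]) for b in BANDS])[:-1]
    for lead, (c1, c2) in clip.channel_lead_map.items():
        W, _ = wavelet.morlet_cwt(
            sub.samples[[c1, c2]],
            1.0 / sub.fs,
            all_periods,
            pad_samples=_cwt_pad(all_periods, sub.fs),
        )
        Wa_parts = np.split(W[0], splits, axis=0)
        Wb_parts = np.split(W[1], splits, axis=0)
        for band, Wa, Wb in zip(BANDS, Wa_parts, Wb_parts):
            v = _xwt_lead_value(Wa, Wb, sub.fs, sub.n_samples)
            key = f"{band}_xwt"
            row[key] = max(row.get(key, 0.0), v)
    if spike_times is None:
        spike_times = detect_spikes(clip, detector_params)
    if window_s is not None:
        lo, hi = window_s
        spike_times = spike_times[(spike_times >= lo) & (spike_times < hi)]
        dur = hi - lo
    else:
        dur = clip.duration_s
    row["spike_rate"] = spike_rate(spike_times, dur)
    row["tod"] = time_of_day(clip.timestamp)
    return row


def build_feature_table(
    catalog: EventCatalog,
    clip_provider,
    cycle: CycleComponent,
    dataset_kind: str,
    visit_dates=None,
    min_rows: int = 200,
    detector_params: SpikeDetectorParams | None = None,
    guard_s: float = 2.0,
    window_len_s: float = 10.0,
    max_rows: int | None = None,
) -> pd.DataFrame:
    """One feature row per stimulation-free SE clip (``dataset_kind=
    "nostim"``, features over the full 90 s) or per post-stimulation window
    (``"poststim"``).

    Rows are labeled with the multidien phase of the clip timestamp and its
    quadrant bin, assigned a clinic-visit segment, log10-transformed (power
    features) and z-scored per segment.  Raises if fewer than ``min_rows``
    rows survive (the study-inclusion criterion).  ``max_rows`` caps the
    number of clips analysed (uniform thinning) for bounded runtimes.
    """
    if dataset_kind not in ("nostim", "poststim"):
        raise ValueError("dataset_kind must be 'nostim' or 'poststim'")
    ses = catalog.ses(stim=(dataset_kind == "poststim")).reset_index(drop=True)
    phases = cycle.phase_at(ses["timestamp"])
    ses = ses[np.isfinite(phases)].reset_index(drop=True)
    if max_rows is not None and len(ses) > max_rows:
        sel = np.linspace(0, len(ses) - 1, max_rows).round().astype(int)
        ses = ses.iloc[np.unique(sel)].reset_index(drop=True)
    visit_dates = (
        pd.DatetimeIndex(visit_dates) if visit_dates is not None
        else pd.DatetimeIndex([])
    )
    rows: list[dict] = []
    n_rejected = 0
    for _, cat_row in ses.iterrows():
        clip = clip_provider(cat_row)
        if clip is None:
            logger.warning("missing clip %s; row skipped", cat_row["event_id"])
            continue
        phase = float(cycle.phase_at([cat_row["timestamp"]])[0])
        if not np.isfinite(phase):
            continue
        seg = int(np.searchsorted(visit_dates, cat_row["timestamp"]))
        base = {
            "event_id": cat_row["event_id"],
            "timestamp": cat_row["timestamp"],
            "phase": phase,
            "bin": assign_phase_bin(phase),
            "segment_id": seg,
        }
        try:
            spikes = detect_spikes(clip, detector_params)
        except ClipRejectedError as exc:
            logger.warning("clip %s rejected: %s", cat_row["event_id"], exc)
            n_rejected += 1
            continue
        if dataset_kind == "nostim":
            feats = compute_feature_row(clip, None, detector_params, spikes)
            rows.append(
                base | feats | {"window_kind": "no_stim_full_clip"}
            )
        else:
            for w in extract_post_stim_windows(clip, guard_s, window_len_s):
                feats = compute_feature_row(clip, w, detector_params, spikes)
                rows.append(base | feats | {"window_kind": "post_stim_window"})
    table = pd.DataFrame(rows)
    if len(table) < min_rows:
        raise InsufficientDataError(
            f"{len(table)} analysis windows < required minimum of {min_rows}"
        )
    for col in POWER_FEATURES:
        table[col] = np.log10(np.maximum(table[col], 1e-300))
    table = zscore_by_segment(table)
    table.attrs["dataset_kind"] = dataset_kind
    table.attrs["n_rejected"] = n_rejected
    return table
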