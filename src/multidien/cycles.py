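"""Multidien cycle extraction from hourly dIEA counts.

Pipeline: preprocess (hourly grid, gap interpolation, segment splitting,
between-visit z-scoring) -> time-averaged wavelet periodogram over 3-60 day
periods -> AR(1) red-noise 99% significance threshold -> peak detection ->
band-limited wavelet reconstruction at each peak -> Hilbert instantaneous
phase -> selection of the component most phase-locked to Long-Episode
(seizure surrogate) times via the phase-locking value (PLV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from . import wavelet
from .types import (
    BIN_LABELS,
    CycleComponent,
    DIEASeries,
    InsufficientDataError,
    NoMultidienCycleError,
    Periodogram,
)

PERIOD_RANGE_DAYS = (3.0, 60.0)
HOURS_PER_DAY = 24
DT_DAYS = 1.0 / HOURS_PER_DAY


@dataclass
class PreprocessOptions:
    max_gap_hours: float = 24.0
    min_segment_days: float = 90.0
    initial_discard_days: float = 28.0


def preprocess_diea(
    timestamps,
    counts,
    visit_dates,
    options: PreprocessOptions | None = None,
) -> DIEASeries:
    """Regularise a raw dIEA record onto an hourly grid and z-score it.

    Gaps up to ``max_gap_hours`` are linearly interpolated and flagged;
    longer gaps split the record into segments, and segments shorter than
    ``min_segment_days`` are discarded (records must span at least three
    months to resolve multidien periods).  The first
    ``initial_discard_days`` are dropped to avoid the post-implant
    stabilisation effect.  Counts are z-scored within clinic-visit
    intervals (intersected with data segments) to absorb detection-
    parameter changes between visits; zero-variance blocks map to 0.
    """
    opt = options or PreprocessOptions()
    ts = pd.DatetimeIndex(timestamps).floor("h")
    order = np.argsort(ts.values)
    ts, raw = ts[order], np.asarray(counts, float)[order]
    if np.any(raw < 0):
        raise ValueError("counts must be non-negative")
    start = ts[0] + pd.Timedelta(days=opt.initial_discard_days)
    keep = ts >= start
    ts, raw = ts[keep], raw[keep]
    if len(ts) == 0:
        raise InsufficientDataError("no data after initial discard window")
    grid = pd.date_range(ts[0], ts[-1], freq="h")
    series = pd.Series(raw, index=ts)
    series = series[~series.index.duplicated(keep="first")].reindex(grid)
    vals = series.to_numpy()
    missing = np.isnan(vals)

    # locate missing runs; interpolate short ones, split on long ones
    seg_break = np.zeros(len(vals), bool)
    if missing.any():
        run_starts = np.flatnonzero(missing & ~np.roll(missing, 1))
        if missing[0]:
            run_starts = np.unique(np.r_[0, run_starts])
        for s in run_starts:
            e = s
            while e < len(vals) and missing[e]:
                e += 1
            if (e - s) > opt.max_gap_hours or s == 0 or e == len(vals):
                seg_break[s:e] = True
        interp_ok = missing & ~seg_break
        idx = np.arange(len(vals))
        vals = vals.copy()
        vals[interp_ok] = np.interp(
            idx[interp_ok], idx[~missing], vals[~missing]
        )
        missing = np.isnan(vals)
    interp_mask = ~seg_break & np.isnan(series.to_numpy()) & ~missing

    # contiguous segments of valid samples
    valid = ~missing
    seg_id = np.full(len(vals), -1, int)
    sid = 0
    i = 0
    min_len = int(opt.min_segment_days * HOURS_PER_DAY)
    while i < len(vals):
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < len(vals) and valid[j]:
            j += 1
        if (j - i) >= min_len:
            seg_id[i:j] = sid
            sid += 1
        i = j
    keep = seg_id >= 0
    if not keep.any():
        raise InsufficientDataError(
            "no segment of at least "
            f"{opt.min_segment_days:g} days survives preprocessing"
        )
    grid, vals = grid[keep], vals[keep]
    interp_mask, seg_id = interp_mask[keep], seg_id[keep]

    visit_dates = pd.DatetimeIndex(visit_dates).sort_values()
    z = np.zeros(len(vals))
    bounds = [grid[0]] + [v for v in visit_dates if grid[0] < v < grid[-1]]
    bounds.append(grid[-1] + pd.Timedelta(hours=1))
    for sid_, sl in _segment_slices(seg_id):
        seg_t = grid[sl]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            m = (seg_t >= lo) & (seg_t < hi)
            if not m.any():
                continue
            block = vals[sl][m]
            sd = block.std()
            zblock = (block - block.mean()) / sd if sd > 0 else np.zeros_like(block)
            zslice = z[sl]
            zslice[m] = zblock
            z[sl] = zslice
    return DIEASeries(
        timestamps=grid,
        counts=vals.astype(int),
        visit_dates=visit_dates,
        interp_mask=interp_mask,
        z=z,
        segment_ids=seg_id,
    )


def _segment_slices(seg_id: np.ndarray):
    for sid in np.unique(seg_id):
        idx = np.flatnonzero(seg_id == sid)
        yield int(sid), slice(int(idx[0]), int(idx[-1]) + 1)


def estimate_ar1(series: DIEASeries) -> float:
    """Pooled lag-1 autocorrelation of the z-scored counts."""
    num = den = 0.0
    for _, sl in _segment_slices(series.segment_ids):
        x = series.z[sl]
        x = x - x.mean()
        num += float(x[:-1] @ x[1:])
        den += float(x @ x)
    alpha = num / den if den > 0 else 0.0
    if alpha >= 0.99:
        warnings.warn("AR(1) coefficient >= 0.99; clamping", stacklevel=2)
        alpha = 0.99
    return max(alpha, 0.0)


def global_wavelet_spectrum(
    series: DIEASeries,
    min_period_days: float = PERIOD_RANGE_DAYS[0],
    max_period_days: float = PERIOD_RANGE_DAYS[1],
    voices: int = 24,
    omega0: float = 6.0,
) -> Periodogram:
    """Time-averaged Morlet wavelet power of the z-scored dIEA series.

    Cone-of-influence samples are excluded from the average; periods longer
    than half the segment length are masked within that segment.  Multi-
    segment records average segment spectra weighted by the number of
    contributing samples.
    """
    if series.z is None:
        raise ValueError("series must be preprocessed (z-scored) first")
    periods = wavelet.period_grid(min_period_days, max_period_days, voices)
    pw_sum = np.zeros(len(periods))
    n_sum = np.zeros(len(periods))
    var_num = var_den = 0.0
    for _, sl in _segment_slices(series.segment_ids):
        x = series.z[sl]
        n = len(x)
        seg_days = n * DT_DAYS
        W, scales = wavelet.morlet_cwt(x, DT_DAYS, periods, omega0)
        valid = wavelet.coi_valid(n, DT_DAYS, scales)
        valid &= (periods <= seg_days / 2.0)[:, None]
        p, n_avg = wavelet.time_averaged_power(W, valid)
        good = n_avg > 0
        pw_sum[good] += p[good] * n_avg[good]
        n_sum += n_avg
        var_num += float(np.var(x)) * n
        var_den += n
    power = np.where(n_sum > 0, pw_sum / np.maximum(n_sum, 1), np.nan)
    return Periodogram(
        periods_days=periods,
        power=power,
        n_avg=n_sum,
        ar1_coef=estimate_ar1(series),
        variance=var_num / var_den if var_den else 1.0,
        omega0=omega0,
    )


def rednoise_threshold(
    series: DIEASeries,
    periodogram: Periodogram | None = None,
    confidence: float = 0.99,
    **spectrum_kwargs,
) -> np.ndarray:
    """Fill in and return the per-period AR(1) red-noise threshold.

    The lag-1 autocorrelation of the analysed series parameterises a
    theoretical AR(1) spectrum scaled to the series variance; the
    threshold is that spectrum times the ``confidence`` chi-square quantile
    over the effective degrees of freedom of time-averaged wavelet power.
    """
    pg = periodogram if periodogram is not None else global_wavelet_spectrum(
        series, **spectrum_kwargs
    )
    pg.rednoise_threshold = wavelet.rednoise_threshold_values(
        pg.ar1_coef,
        pg.variance,
        DT_DAYS,
        pg.periods_days,
        pg.n_avg,
        confidence,
        pg.omega0,
    )
    return pg.rednoise_threshold


def find_significant_peaks(
    periodogram: Periodogram, merge_octaves: float = 0.25
) -> list[tuple[float, float]]:
    """Local power maxima strictly above the red-noise threshold.

    Maxima within ``merge_octaves`` of each other are merged keeping the
    higher; the result is sorted by power descending and also stored on the
    periodogram.  An empty list is a valid outcome (no multidien cycle).
    """
    if periodogram.rednoise_threshold is None:
        raise ValueError("compute the red-noise threshold first")
    p = periodogram.power
    thr = periodogram.rednoise_threshold
    per = periodogram.periods_days
    cand = []
    for i in range(1, len(p) - 1):
        if not np.isfinite(p[i]) or p[i] <= thr[i]:
            continue
        left = p[i - 1] if np.isfinite(p[i - 1]) else -np.inf
        right = p[i + 1] if np.isfinite(p[i + 1]) else -np.inf
        if p[i] > left and p[i] >= right:
            cand.append((float(per[i]), float(p[i])))
    cand.sort(key=lambda t: -t[1])
    merged: list[tuple[float, float]] = []
    for period, power in cand:
        if all(
            abs(math.log2(period / mp)) >= merge_octaves for mp, _ in merged
        ):
            merged.append((period, power))
    periodogram.peaks = merged
    return merged


def reconstruct_cycle(
    series: DIEASeries,
    peak_period_days: float,
    bandwidth_octaves: float = 1.0 / 3.0,
    voices: int = 24,
    omega0: float = 6.0,
) -> CycleComponent:
    """Band-limited inverse wavelet reconstruction around one peak period.

    Scales within ``+-bandwidth_octaves`` of the peak are summed; the
    instantaneous phase comes from the analytic (Hilbert) signal per
    segment, so phase 0 coincides with local maxima of the component.
    """
    if not (PERIOD_RANGE_DAYS[0] <= peak_period_days <= PERIOD_RANGE_DAYS[1]):
        raise ValueError("peak period outside the multidien range")
    band = peak_period_days * 2.0 ** np.array(
        [-bandwidth_octaves, bandwidth_octaves]
    )
    periods = wavelet.period_grid(band[0], band[1], voices)
    signal = np.zeros(len(series))
    phase = np.zeros(len(series))
    for _, sl in _segment_slices(series.segment_ids):
        x = series.z[sl]
        W, scales = wavelet.morlet_cwt(x, DT_DAYS, periods, omega0)
        valid = wavelet.coi_valid(len(x), DT_DAYS, scales)
        if valid.mean() < 0.5:
            warnings.warn(
                f"period {peak_period_days:.1f} d: cone of influence covers "
                ">50% of a segment",
                stacklevel=2,
            )
        rec = wavelet.reconstruct(W, scales, 1.0 / voices, DT_DAYS)
        rec = rec - rec.mean()
        signal[sl] = rec
        phase[sl] = np.angle(hilbert(rec))
    return CycleComponent(
        period_days=float(peak_period_days),
        timestamps=series.timestamps,
        signal=signal,
        phase=phase,
        segment_ids=series.segment_ids,
    )


def phase_locking_value(phases) -> float:
    """Mean resultant length ``|mean(exp(i*phase))|`` of event phases."""
    phases = np.asarray(phases, float)
    phases = phases[np.isfinite(phases)]
    if phases.size == 0:
        raise ValueError("no events: PLV undefined")
    return float(np.abs(np.exp(1j * phases).mean()))


def select_seizure_locked_cycle(
    series: DIEASeries,
    peaks: list[tuple[float, float]],
    le_times,
    **reconstruct_kwargs,
) -> CycleComponent:
    """Among significant periodogram peaks, return the reconstructed
    component whose phase is most locked to LE (seizure surrogate) times.

    Each LE is assigned the phase of its nearest hourly sample; ties in PLV
    break toward the shorter period.  Raises if there is no significant
    peak (the patient-exclusion criterion) or no LE falls inside the
    analysed segments.
    """
    if not peaks:
        raise NoMultidienCycleError("no significant multidien cycle")
    le_times = pd.DatetimeIndex(le_times)
    best: CycleComponent | None = None
    for period, _ in sorted(peaks):  # ascending period; strict > keeps shorter
        comp = reconstruct_cycle(series, period, **reconstruct_kwargs)
        ph = comp.phase_at(le_times)
        ph = ph[np.isfinite(ph)]
        if ph.size == 0:
            raise InsufficientDataError(
                "no LE events inside the analysed segments"
            )
        plv = phase_locking_value(ph)
        if best is None or plv > best.plv:
            comp.plv = plv
            comp.le_phases = ph
            best = comp
    return best


def assign_phase_bin(phase) -> np.ndarray | str:
    """Map phase (radians) to the four quadrant bins.

    Half-open arcs: peak ``[-pi/4, pi/4)``, falling ``[pi/4, 3pi/4)``,
    trough ``[3pi/4, pi] u (-pi, -3pi/4)``, rising ``[-3pi/4, -pi/4)``.
    """
    arr = np.asarray(phase, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite phase")
    wrapped = np.mod(arr + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    k = np.floor((wrapped + np.pi / 4.0) / (np.pi / 2.0)).astype(int) % 4
    labels = np.array(BIN_LABELS)[k]
    return labels if arr.ndim else str(labels)


def omnibus_uniformity_test(phases) -> float:
    """Hodges-Ajne omnibus test p-value for circular non-uniformity.

    ``m`` is the minimum number of points in any closed half-circle; the
    exact tail ``p = (n - 2m) C(n, m) 2^(1-n)`` is used in its validity
    region ``m < n/3``.  For ``m >= n/3`` the distribution is nearly
    uniform and p is reported as 1 (documented approximation).
    """
    phases = np.asarray(phases, float)
    phases = phases[np.isfinite(phases)]
    n = phases.size
    if n < 5:
        raise ValueError("too few events for the omnibus test (need >= 5)")
    ang = np.sort(np.mod(phases, 2.0 * np.pi))
    ext = np.concatenate([ang, ang + 2.0 * np.pi])
    counts = np.searchsorted(ext, ang + np.pi, side="left") - np.arange(n)
    m = int(min(counts.min(), (n - counts).min()))
    if m >= n / 3.0:
        return 1.0
    logp = (
        math.log(n - 2 * m)
        + math.lgamma(n + 1)
        - math.lgamma(m + 1)
        - math.lgamma(n - m + 1)
        + (1 - n) * math.log(2.0)
    )
    return float(min(1.0, math.exp(logp)))
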