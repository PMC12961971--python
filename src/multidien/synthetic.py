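"""Device-realistic synthetic data for the whole analysis chain.

Emulates the data streams of an RNS-class implant with known ground truth:

* hourly dIEA counts — Poisson with a log-linear rate carrying a multidien
  cycle, a circadian cycle and AR(1) log-noise;
* Long Episodes (seizure surrogates) von-Mises phase-locked to the rising
  phase of the multidien cycle;
* twice-daily Scheduled Events with phase-dependent dropout (device memory
  pressure) and phase-dependent stimulation probability;
* 90-s 4-channel EEG clips: 1/f background, band-limited oscillations whose
  amplitude and within-lead coherence are phase-modulated, injected
  interictal-spike templates at a phase-modulated rate, day/night power
  shift, and high-amplitude stimulation artifacts.

Every stage derives its randomness from ``config.seed`` so the downstream
parameter-recovery tests are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, sosfiltfilt
from scipy.special import expit

from .types import ConfigurationError, DIEASeries, EEGClip, EventCatalog
from .cycles import assign_phase_bin

EPOCH = pd.Timestamp("2020-01-06 00:00:00")  # a Monday, arbitrary fixed origin

#: Narrowband oscillation centre frequencies (Hz), one per canonical band.
BAND_CENTERS = {"theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 60.0}
#: Baseline RMS amplitude (µV) of each band oscillation.
BAND_AMPLITUDES = {"theta": 6.0, "alpha": 5.0, "beta": 3.0, "gamma": 1.5}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic patient.

    Rate modulations act on the log scale (``exp(a * cos(phase))``), so any
    finite depth keeps rates strictly positive.  A zero ``se_dropout_gain``
    or ``stim_prob_gain`` disables that mechanism entirely.
    """

    duration_days: float = 730.0
    multidien_period_days: float = 21.0
    multidien_depth: float = 0.5  # a_m, log-rate modulation amplitude
    circadian_depth: float = 0.3  # a_c
    ar1_coef: float = 0.8
    ar1_sd: float = 0.25  # stationary SD of the AR(1) log-rate noise
    base_rate_per_hour: float = 50.0
    le_rate_per_day: float = 0.3
    le_kappa: float = 1.0
    le_mean_phase: float = -np.pi / 2.0  # rising phase
    se_times_local: tuple[int, int] = (10, 22)  # clock hours, 12 h apart
    se_dropout_gain: float = 1.0
    se_dropout_bias: float = -1.5
    stim_prob_gain: float = 1.5
    stim_prob_bias: float = 0.0
    visit_interval_days: float = 90.0
    clip_fs_hz: float = 250.0
    clip_duration_s: float = 90.0
    band_mod_gains: dict[str, float] = field(
        default_factory=lambda: {
            "theta": 0.4, "alpha": 0.5, "beta": 0.4, "gamma": 0.3
        }
    )
    coherence_base: float = 0.4
    coherence_gain: float = 0.2
    #: between-clip variability of real EEG: log-normal amplitude jitter
    #: shared by all bands of a clip, per-band log-normal jitter, and
    #: additive jitter of the within-lead coherence level
    amp_jitter_log_sd: float = 0.5
    band_jitter_log_sd: float = 0.3
    coherence_jitter_sd: float = 0.15
    spike_base_rate_per_min: float = 1.0
    spike_mod_gain: float = 0.5
    tod_power_shift: float = 0.2
    background_sd_uv: float = 10.0
    spike_amplitude_sds: float = 8.0
    poststim_mod_factor: float = 0.5  # modulation gain attenuation after stim
    seed: int = 0

    def validate(self) -> None:
        if self.duration_days <= 0 or self.base_rate_per_hour <= 0:
            raise ConfigurationError("durations and rates must be positive")
        if not (3.0 <= self.multidien_period_days <= 60.0):
            raise ConfigurationError("multidien period must be in [3, 60] d")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ConfigurationError("ar1_coef must be in [0, 1)")
        if self.le_kappa < 0:
            raise ConfigurationError("von Mises concentration must be >= 0")
        if self.multidien_depth < 0 or self.circadian_depth < 0:
            raise ConfigurationError("modulation depths must be >= 0")
        peak_log = (
            np.log(self.base_rate_per_hour)
            + self.multidien_depth + self.circadian_depth + 6 * self.ar1_sd
        )
        if not np.isfinite(np.exp(peak_log)):
            raise ConfigurationError("rate model overflows: non-finite rates")


@dataclass
class GroundTruth:
    """True simulation state used as the oracle for recovery tests."""

    config: SimulationConfig
    start: pd.Timestamp
    le_times: pd.DatetimeIndex | None = None
    le_phases: np.ndarray | None = None
    se_truth: pd.DataFrame | None = None  # event_id, true_phase, true_bin
    clip_spike_times: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def true_period_days(self) -> float:
        return self.config.multidien_period_days

    def phase_fn(self, times) -> np.ndarray:
        """True multidien phase (radians, phase 0 = cycle peak) at ``times``.

        Accepts timestamps or hours-since-start; 2*pi-periodic with the
        configured period.
        """
        if isinstance(times, (pd.Timestamp, pd.DatetimeIndex)) or (
            np.asarray(times).dtype.kind == "M"
        ):
            hours = (
                pd.DatetimeIndex(np.atleast_1d(times)) - self.start
            ).total_seconds() / 3600.0
            hours = np.asarray(hours)
        else:
            hours = np.asarray(times, float)
        phase = 2.0 * np.pi * (hours / 24.0) / self.config.multidien_period_days
        out = np.mod(phase + np.pi, 2.0 * np.pi) - np.pi
        out = np.where(out == -np.pi, np.pi, out)
        return out if out.ndim else float(out)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _log_rate_modulation(config, hours: np.ndarray, gt: GroundTruth):
    """Deterministic part of the log-rate (multidien + circadian terms)."""
    phase = gt.phase_fn(hours)
    hod = np.mod(hours, 24.0)
    circ = np.cos(2.0 * np.pi * (hod - 3.0) / 24.0)  # nocturnal circadian peak
    return config.multidien_depth * np.cos(phase) + config.circadian_depth * circ


def simulate_diea(config: SimulationConfig) -> tuple[DIEASeries, GroundTruth]:
    """Hourly Poisson dIEA counts with multidien/circadian/AR(1) log-rate.

    ``log lambda(t) = log(base) + a_m cos(phase(t)) + a_c cos(2 pi t/24h)
    + AR(1) noise``; counts are Poisson(lambda).  Clinic visits are placed
    every ``visit_interval_days``.
    """
    config.validate()
    gt = GroundTruth(config=config, start=EPOCH)
    n = int(round(config.duration_days * 24))
    hours = np.arange(n, dtype=float)
    rng = _rng(config, 0)
    log_rate = np.log(config.base_rate_per_hour) + _log_rate_modulation(
        config, hours, gt
    )
    if config.ar1_sd > 0:
        innov_sd = config.ar1_sd * np.sqrt(1.0 - config.ar1_coef ** 2)
        eps = innov_sd * rng.standard_normal(n)
        eps[0] = config.ar1_sd * rng.standard_normal()
        noise = lfilter([1.0], [1.0, -config.ar1_coef], eps)
        log_rate = log_rate + noise
    lam = np.exp(log_rate)
    if not np.all(np.isfinite(lam)):
        raise ConfigurationError("non-finite Poisson rates")
    counts = rng.poisson(lam)
    timestamps = EPOCH + pd.to_timedelta(hours, unit="h")
    n_visits = int(config.duration_days // config.visit_interval_days)
    visits = EPOCH + pd.to_timedelta(
        (np.arange(1, n_visits + 1)) * config.visit_interval_days, unit="D"
    )
    series = DIEASeries(
        timestamps=pd.DatetimeIndex(timestamps),
        counts=counts,
        visit_dates=pd.DatetimeIndex(visits),
    )
    return series, gt


def simulate_les(
    ground_truth: GroundTruth, config: SimulationConfig | None = None
) -> pd.DatetimeIndex:
    """LE (seizure surrogate) times phase-locked to the multidien cycle.

    Event times follow an intensity proportional to
    ``exp(kappa cos(phase - mu))``, so event phases are von Mises with mean
    ``le_mean_phase`` and concentration ``le_kappa`` (uniform when kappa=0).
    Drawn by rejection sampling against the uniform envelope.
    """
    config = config or ground_truth.config
    if config.le_kappa < 0:
        raise ConfigurationError("von Mises concentration must be >= 0")
    rng = _rng(config, 1)
    n_events = rng.poisson(config.le_rate_per_day * config.duration_days)
    times: list[np.ndarray] = []
    need = n_events
    while need > 0:
        batch = max(64, int(need * np.exp(config.le_kappa) * 1.2))
        batch = min(batch, 2_000_000)
        t = rng.uniform(0.0, config.duration_days * 24.0, size=batch)
        u = rng.uniform(size=batch)
        accept = u < np.exp(
            config.le_kappa
            * (np.cos(ground_truth.phase_fn(t) - config.le_mean_phase) - 1.0)
        )
        got = t[accept][:need]
        times.append(got)
        need -= len(got)
    hours = np.sort(np.concatenate(times)) if times else np.array([])
    le_times = pd.DatetimeIndex(EPOCH + pd.to_timedelta(hours, unit="h"))
    ground_truth.le_times = le_times
    ground_truth.le_phases = ground_truth.phase_fn(hours)
    return le_times


def simulate_se_catalog(
    ground_truth: GroundTruth, config: SimulationConfig | None = None
) -> EventCatalog:
    """Scheduled-Event catalog with phase-biased dropout and stimulation.

    SEs occur at the two daily clock times.  Each is dropped with
    probability ``sigmoid(bias + gain * cos(phase))`` (zero gain disables
    dropout), emulating overwriting of low-priority clips when the device
    is busy near cycle peaks.  Surviving SEs are flagged as stimulated with
    probability logistic in the deterministic log-rate modulation (zero
    gain disables stimulation); stimulated clips get 1-4 stim offsets
    within the 90-s clip.
    """
    config = config or ground_truth.config
    rng = _rng(config, 2)
    days = np.arange(int(config.duration_days))
    slots = np.sort(
        np.concatenate([days * 24.0 + h for h in config.se_times_local])
    )
    slots = slots[slots < config.duration_days * 24.0]
    phases = ground_truth.phase_fn(slots)
    if config.se_dropout_gain != 0.0:
        p_drop = expit(
            config.se_dropout_bias + config.se_dropout_gain * np.cos(phases)
        )
        keep = rng.uniform(size=len(slots)) >= p_drop
    else:
        keep = np.ones(len(slots), bool)
    slots, phases = slots[keep], phases[keep]
    if config.stim_prob_gain != 0.0:
        mod = _log_rate_modulation(config, slots, ground_truth)
        p_stim = expit(config.stim_prob_bias + config.stim_prob_gain * mod)
        has_stim = rng.uniform(size=len(slots)) < p_stim
    else:
        has_stim = np.zeros(len(slots), bool)
    offsets: list[list[float]] = []
    max_off = config.clip_duration_s - 15.0
    for stim in has_stim:
        if not stim:
            offsets.append([])
            continue
        k = int(min(1 + rng.poisson(1.0), 4))
        offsets.append(sorted(rng.uniform(5.0, max_off, size=k).tolist()))
    ids = [f"SE{i:06d}" for i in range(len(slots))]
    frame = pd.DataFrame(
        {
            "event_id": ids,
            "timestamp": pd.DatetimeIndex(
                EPOCH + pd.to_timedelta(slots, unit="h")
            ),
            "type": "SE",
            "has_stim": has_stim,
            "stim_offsets_s": offsets,
        }
    )
    ground_truth.se_truth = pd.DataFrame(
        {
            "event_id": ids,
            "true_phase": phases,
            "true_bin": assign_phase_bin(phases),
        }
    )
    return EventCatalog(frame=frame)


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic interictal-spike template: sharp 30-ms negative deflection
    followed by a slower 40-ms positive wave; peak amplitude 1."""
    n_sharp = max(int(round(0.030 * fs)), 3)
    n_slow = max(int(round(0.040 * fs)), 3)
    sharp = -np.hanning(n_sharp)
    slow = 0.45 * np.hanning(n_slow)
    return np.concatenate([sharp, slow])


def _narrowband(rng, n, fs, center):
    """Unit-RMS band-limited noise around ``center`` Hz (+-15%)."""
    lo, hi = center * 0.85, center * 1.15
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _pink_noise(rng, n):
    """Unit-RMS 1/f-power background via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** -0.5
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / np.sqrt(np.mean(x ** 2))


def synthesize_clip(
    true_phase: float,
    tod: int,
    has_stim: bool,
    config: SimulationConfig,
    seed,
    stim_offsets_s=(),
    timestamp: pd.Timestamp | None = None,
    attenuate_modulation: bool = False,
) -> tuple[EEGClip, np.ndarray]:
    """One 4-channel SE clip plus its true injected spike times (s).

    Band oscillation amplitudes follow ``A_b (1 + g_b cos(phase))`` (clamped
    at 0) and within-lead coherence follows
    ``coherence_base + coherence_gain cos(phase)``; spikes are injected at
    rate ``spike_base exp(spike_mod cos(phase))`` per minute; a day/night
    multiplicative power shift is applied via ``tod``.  With
    ``attenuate_modulation`` the phase-modulation gains are scaled by
    ``poststim_mod_factor`` (the stimulation-response attenuation).
    """
    rng = np.random.default_rng(seed)
    fs, dur = config.clip_fs_hz, config.clip_duration_s
    n = int(round(fs * dur))
    factor = config.poststim_mod_factor if attenuate_modulation else 1.0
    tod_gain = np.exp(config.tod_power_shift * (float(tod) - 0.5))
    samples = np.empty((4, n))
    for ch in range(4):
        samples[ch] = config.background_sd_uv * _pink_noise(rng, n)
    rho = float(
        np.clip(
            config.coherence_base
            + factor * config.coherence_gain * np.cos(true_phase)
            + config.coherence_jitter_sd * rng.standard_normal(),
            0.0,
            0.98,
        )
    )
    clip_amp_jitter = np.exp(
        config.amp_jitter_log_sd * rng.standard_normal()
    )
    for band, center in BAND_CENTERS.items():
        gain = factor * config.band_mod_gains.get(band, 0.0)
        band_jitter = np.exp(
            config.band_jitter_log_sd * rng.standard_normal()
        )
        amp = BAND_AMPLITUDES[band] * max(
            1.0 + gain * np.cos(true_phase), 0.0
        ) * tod_gain * clip_amp_jitter * band_jitter
        if amp == 0.0:
            continue
        for lead, (c1, c2) in (("lead1", (0, 1)), ("lead2", (2, 3))):
            shared = _narrowband(rng, n, fs, center)
            for ch in (c1, c2):
                private = _narrowband(rng, n, fs, center)
                osc = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * private
                samples[ch] += amp * osc

    # interictal spikes (strongest on the detection channels); amplitude is
    # defined against the robust SD of the composite background each
    # channel actually carries (1/f + oscillations)
    rate = config.spike_base_rate_per_min * np.exp(
        factor * config.spike_mod_gain * np.cos(true_phase)
    )
    n_spikes = rng.poisson(rate * dur / 60.0)
    bg_sd = 1.4826 * np.median(
        np.abs(samples - np.median(samples, axis=1, keepdims=True)), axis=1
    )
    template = _spike_template(fs)
    spike_times = []
    guard = 1.0
    for _ in range(n_spikes):
        for _attempt in range(20):
            t = rng.uniform(0.5, dur - 0.5)
            if all(abs(t - o) > guard for o in stim_offsets_s):
                break
        else:
            continue
        i0 = int(round(t * fs))
        seg = slice(i0, min(i0 + len(template), n))
        tpl = template[: seg.stop - seg.start]
        for ch in range(4):
            w = 1.0 if ch in (0, 2) else 0.4
            samples[ch, seg] += (
                w * config.spike_amplitude_sds * bg_sd[ch] * tpl
            )
        spike_times.append(t)

    if has_stim:
        art_n = int(round(0.100 * fs))
        burst = (
            20.0
            * config.background_sd_uv
            * np.sin(2.0 * np.pi * 100.0 * np.arange(art_n) / fs)
            * np.hanning(art_n)
        )
        for off in stim_offsets_s:
            i0 = int(round(off * fs))
            seg = slice(i0, min(i0 + art_n, n))
            samples[:, seg] += burst[: seg.stop - seg.start]

    clip = EEGClip(
        samples=samples,
        fs=fs,
        timestamp=timestamp if timestamp is not None else EPOCH,
        clip_type="SE",
        stim_offsets_s=list(stim_offsets_s),
    )
    return clip, np.sort(np.asarray(spike_times))


def clip_seed(config: SimulationConfig, event_id: str) -> np.random.SeedSequence:
    """Deterministic per-clip seed derived from the patient seed."""
    return np.random.SeedSequence(
        entropy=config.seed, spawn_key=(3, int(event_id.lstrip("SEL")))
    )


def make_clip_provider(ground_truth: GroundTruth, config: SimulationConfig):
    """Return ``provider(catalog_row) -> EEGClip`` synthesizing clips lazily.

    Stimulated clips carry attenuated phase modulation (the simulated
    stimulation response).  Injected spike times are recorded in
    ``ground_truth.clip_spike_times``.
    """
    truth = ground_truth.se_truth.set_index("event_id")

    def provider(row) -> EEGClip:
        eid = row["event_id"]
        phase = float(truth.loc[eid, "true_phase"])
        ts = row["timestamp"]
        tod = 1 if 8 <= ts.hour < 20 else 0
        clip, spikes = synthesize_clip(
            phase,
            tod,
            bool(row["has_stim"]),
            config,
            clip_seed(config, eid),
            stim_offsets_s=row["stim_offsets_s"],
            timestamp=ts,
            attenuate_modulation=bool(row["has_stim"]),
        )
        ground_truth.clip_spike_times[eid] = spikes
        return clip

    return provider


def with_overrides(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Functional config update (dataclass ``replace`` convenience)."""
    return replace(config, **kwargs)
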