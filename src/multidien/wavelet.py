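"""Complex Morlet continuous wavelet transform with red-noise significance.

The transform is computed in the frequency domain with the scale
normalisation under which the expected wavelet power of a stationary
process equals its Fourier spectrum, so that time-averaged power can be
tested against an AR(1) ("red noise") null via a chi-square quantile with
an effective-degrees-of-freedom correction for time averaging.  The same
engine serves the multidien periodogram (dt in days) and the cross-wavelet
EEG connectivity features (dt in seconds).
"""

from __future__ import annotations

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.stats import chi2

#: Reconstruction factor C_delta for the Morlet(omega0=6) wavelet.
C_DELTA = 0.776
#: Decorrelation length factor gamma for Morlet(6) time averaging.
GAMMA_DECORR = 2.32
#: psi_0(0) = pi^(-1/4) for the Morlet wavelet.
PSI0 = np.pi ** -0.25


def fourier_factor(omega0: float = 6.0) -> float:
    """Ratio of Fourier period to wavelet scale for the Morlet wavelet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))


def period_grid(
    min_period: float, max_period: float, voices: int = 24
) -> np.ndarray:
    """Log-spaced periods from ``min_period`` to ``max_period`` inclusive,
    with ``voices`` periods per octave."""
    n = int(np.ceil(np.log2(max_period / min_period) * voices))
    grid = min_period * 2.0 ** (np.arange(n + 1) / voices)
    return grid[grid <= max_period * (1 + 1e-12)]


_BANK_CACHE: dict[tuple, np.ndarray] = {}
_BANK_CACHE_MAX = 8


def _filter_bank(
    nfft: int, dt: float, scales: np.ndarray, omega0: float
) -> np.ndarray:
    key = (nfft, float(dt), scales.tobytes(), float(omega0))
    bank = _BANK_CACHE.get(key)
    if bank is None:
        omega = 2.0 * np.pi * np.fft.fftfreq(nfft, dt)
        arg = scales[:, None] * omega[None, :] - omega0
        bank = PSI0 * np.exp(-0.5 * arg ** 2) * (omega[None, :] > 0)
        bank *= np.sqrt(2.0 * np.pi * scales[:, None] / dt)
        if len(_BANK_CACHE) >= _BANK_CACHE_MAX:
            _BANK_CACHE.pop(next(iter(_BANK_CACHE)))
        _BANK_CACHE[key] = bank
    return bank


def morlet_cwt(
    x: np.ndarray,
    dt: float,
    periods: np.ndarray,
    omega0: float = 6.0,
    pad_samples: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CWT of ``x`` at the Fourier periods given (same time unit as ``dt``).

    ``x`` may be 1-D ``(n,)`` or 2-D ``(channels, n)``; the result has shape
    ``(nscales, n)`` or ``(channels, nscales, n)``.  The series is
    mean-removed and zero-padded to avoid wraparound; ``pad_samples``
    (default: the series length) may be shortened when the longest wavelet
    is much briefer than the series.  Returns ``(W, scales)``.
    """
    x = np.atleast_2d(np.asarray(x, float))
    n = x.shape[-1]
    periods = np.asarray(periods, float)
    scales = periods / fourier_factor(omega0)
    nfft = next_fast_len(n + (n if pad_samples is None else int(pad_samples)))
    xhat = fft(x - x.mean(axis=-1, keepdims=True), nfft, axis=-1)
    bank = _filter_bank(nfft, dt, scales, omega0)
    W = ifft(xhat[:, None, :] * bank[None, :, :], axis=-1)[..., :n]
    if W.shape[0] == 1:
        W = W[0]
    return W, scales


def coi_valid(n: int, dt: float, scales: np.ndarray) -> np.ndarray:
    """Boolean ``(nscales, n)`` mask, True where the sample lies outside the
    cone of influence (distance to the nearer edge exceeds the e-folding
    time ``sqrt(2)*scale``)."""
    t_edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    return t_edge[None, :] >= np.sqrt(2.0) * np.asarray(scales)[:, None]


def time_averaged_power(
    W: np.ndarray, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean ``|W|^2`` per scale over valid samples; returns (power, n_avg)."""
    p = np.abs(W) ** 2
    if valid is None:
        return p.mean(axis=-1), np.full(p.shape[0], p.shape[-1])
    n_avg = valid.sum(axis=-1)
    power = np.where(n_avg > 0, (p * valid).sum(axis=-1) / np.maximum(n_avg, 1),
                     np.nan)
    return power, n_avg


def ar1_spectrum(alpha: float, dt: float, periods: np.ndarray) -> np.ndarray:
    """Normalised AR(1) power spectrum at the Fourier periods given.

    ``P(f) = (1 - alpha^2) / (1 + alpha^2 - 2 alpha cos(2 pi f dt))``, which
    integrates to 1 over frequency so it scales directly by the series
    variance.  ``alpha = 0`` gives a flat (white) spectrum.
    """
    freq = dt / np.asarray(periods, float)  # cycles per sample
    return (1.0 - alpha ** 2) / (
        1.0 + alpha ** 2 - 2.0 * alpha * np.cos(2.0 * np.pi * freq)
    )


def rednoise_threshold_values(
    alpha: float,
    variance: float,
    dt: float,
    periods: np.ndarray,
    n_avg: np.ndarray,
    confidence: float = 0.99,
    omega0: float = 6.0,
) -> np.ndarray:
    """Per-period threshold for time-averaged wavelet power under AR(1).

    The time-averaged power at scale ``s`` over ``n_avg`` samples is
    distributed as ``variance * P(f) * chi2_nu / nu`` with
    ``nu = 2 sqrt(1 + (n_avg dt / (gamma s))^2)``.
    """
    periods = np.asarray(periods, float)
    scales = periods / fourier_factor(omega0)
    n_avg = np.asarray(n_avg, float)
    dof = 2.0 * np.sqrt(1.0 + (n_avg * dt / (GAMMA_DECORR * scales)) ** 2)
    dof = np.maximum(dof, 2.0)
    spec = variance * ar1_spectrum(alpha, dt, periods)
    thr = spec * chi2.ppf(confidence, dof) / dof
    thr[n_avg <= 0] = np.inf
    return thr


def reconstruct(
    W: np.ndarray, scales: np.ndarray, dj: float, dt: float
) -> np.ndarray:
    """Inverse transform summing the given scales (band-limited if ``W``
    holds only a subset of scales)."""
    factor = dj * np.sqrt(dt) / (C_DELTA * PSI0)
    return factor * (W.real / np.sqrt(scales)[:, None]).sum(axis=0)
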