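"""Cycle extraction: preprocessing, periodogram, red noise, phase, PLV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import hourly_sinusoid, make_series
from multidien import cycles, wavelet
from multidien.types import InsufficientDataError, NoMultidienCycleError


def _raw_record(days=300, base=50.0, seed=0, visit_every=90):
    rng = np.random.default_rng(seed)
    n = days * 24
    ts = pd.date_range("2020-01-06", periods=n, freq="h")
    counts = rng.poisson(base, n)
    visits = pd.date_range(
        ts[0], ts[-1], freq=pd.Timedelta(days=visit_every)
    )[1:]
    return ts, counts, visits


class TestPreprocess:
    def test_short_gap_interpolated_and_flagged(self):
        ts, counts, visits = _raw_record(days=200)
        keep = np.ones(len(ts), bool)
        gap = slice(50 * 24, 50 * 24 + 6)
        keep[gap] = False
        s = cycles.preprocess_diea(ts[keep], counts[keep], visits)
        assert s.interp_mask.sum() == 6
        assert s.interp_fraction == pytest.approx(6 / len(s))
        # grid is strictly hourly
        assert (np.diff(s.timestamps.values) == np.timedelta64(1, "h")).all()

    def test_long_gap_splits_and_short_segment_discarded(self):
        ts, counts, visits = _raw_record(days=268)  # 28 discarded + 240
        keep = np.ones(len(ts), bool)
        # after the 28-d initial discard: 160 d data, 40 d gap, 40 d data
        start = (28 + 160) * 24
        keep[start: start + 40 * 24] = False
        s = cycles.preprocess_diea(ts[keep], counts[keep], visits)
        ids = np.unique(s.segment_ids)
        assert len(ids) == 1  # 40-d tail < 90-d minimum: discarded
        assert len(s) == pytest.approx(160 * 24, abs=24)

    def test_constant_segment_zscores_to_zero(self):
        ts, counts, visits = _raw_record(days=200)
        s = cycles.preprocess_diea(ts, np.full(len(ts), 42), visits)
        assert np.all(s.z == 0.0)

    def test_visit_blocks_are_standardised(self):
        ts, counts, visits = _raw_record(days=300)
        s = cycles.preprocess_diea(ts, counts, visits)
        bounds = [s.timestamps[0], *visits,
                  s.timestamps[-1] + pd.Timedelta(hours=1)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            m = (s.timestamps >= lo) & (s.timestamps < hi)
            if m.sum() > 100:
                assert abs(s.z[m].mean()) < 1e-10
                assert s.z[m].std() == pytest.approx(1.0, abs=1e-6)

    def test_nothing_survives_raises(self):
        ts, counts, visits = _raw_record(days=60)
        with pytest.raises(InsufficientDataError):
            cycles.preprocess_diea(ts, counts, visits)


class TestGlobalWaveletSpectrum:
    def test_pure_21d_sinusoid_peak_location(self):
        s = make_series(hourly_sinusoid(21.0, 730))
        pg = cycles.global_wavelet_spectrum(s)
        best = pg.periods_days[np.nanargmax(pg.power)]
        assert 19.5 <= best <= 22.5

    def test_two_component_input_yields_two_maxima(self):
        z = hourly_sinusoid(7.0, 730) + hourly_sinusoid(30.0, 730)
        pg = cycles.global_wavelet_spectrum(make_series(z))
        cycles.rednoise_threshold(make_series(z), pg)
        peaks = cycles.find_significant_peaks(pg)
        assert len(peaks) == 2
        found = sorted(p for p, _ in peaks)
        assert found[0] == pytest.approx(7.0, rel=0.12)
        assert found[1] == pytest.approx(30.0, rel=0.12)

    def test_peak_location_cross_checked_against_pywavelets(self):
        """Independent oracle: PyWavelets' complex Morlet CWT localises the
        same dominant period as the in-package transform on a pure tone."""
        pywt = pytest.importorskip("pywt")
        fs = 100.0
        t = np.arange(0, 30, 1 / fs)
        x = np.cos(2 * np.pi * 5.0 * t)  # 0.2-s period
        periods = wavelet.period_grid(1 / 20.0, 1 / 2.0, 12)
        W, _ = wavelet.morlet_cwt(x, 1 / fs, periods)
        mine = periods[np.argmax((np.abs(W) ** 2).mean(axis=1))]
        # pywt's cmor center frequency C (cycles) maps to omega0 = 2 pi C
        C = 6.0 / (2 * np.pi)
        scales = C / (1.0 / periods) * fs
        coef, freqs = pywt.cwt(x, scales, f"cmor1.5-{C}",
                               sampling_period=1 / fs)
        theirs = 1.0 / freqs[np.argmax((np.abs(coef) ** 2).mean(axis=1))]
        assert mine == pytest.approx(0.2, rel=0.05)
        assert theirs == pytest.approx(0.2, rel=0.05)
        assert mine == pytest.approx(theirs, rel=0.05)

    def test_white_noise_has_no_systematic_peak(self):
        rng = np.random.default_rng(5)
        n_sig = 0
        for rep in range(20):
            s = make_series(rng.standard_normal(730 * 24))
            pg = cycles.global_wavelet_spectrum(s)
            cycles.rednoise_threshold(s, pg)
            n_sig += bool(cycles.find_significant_peaks(pg))
        assert n_sig <= 4  # 99% pointwise level, ~100 periods probed


class TestRedNoise:
    def test_white_noise_spectrum_flat(self):
        periods = wavelet.period_grid(3, 60, 24)
        spec = wavelet.ar1_spectrum(0.0, 1 / 24, periods)
        assert spec.max() / spec.min() == pytest.approx(1.0, abs=1e-12)

    def test_ar1_spectrum_closed_form_ratio(self):
        a = 0.7
        for p1, p2 in [(5.0, 20.0), (3.0, 60.0)]:
            got = wavelet.ar1_spectrum(a, 1 / 24, np.array([p1]))[0] / \
                wavelet.ar1_spectrum(a, 1 / 24, np.array([p2]))[0]
            f1, f2 = (1 / 24) / p1, (1 / 24) / p2
            want = (1 + a**2 - 2 * a * np.cos(2 * np.pi * f2)) / (
                1 + a**2 - 2 * a * np.cos(2 * np.pi * f1)
            )
            assert got == pytest.approx(want, rel=1e-6)

    def test_ar1_calibration_quick(self):
        """Pointwise 99% threshold exceeded at ~1% of (rep, period) cells
        on pure AR(1) input (reduced Monte-Carlo; the full calibration runs
        in the acceptance suite)."""
        from scipy.signal import lfilter

        rng = np.random.default_rng(11)
        alpha, n = 0.8, 730 * 24
        hits = total = 0
        for _ in range(25):
            eps = rng.standard_normal(n) * np.sqrt(1 - alpha**2)
            x = lfilter([1.0], [1.0, -alpha], eps)
            s = make_series((x - x.mean()) / x.std())
            pg = cycles.global_wavelet_spectrum(s)
            thr = cycles.rednoise_threshold(s, pg)
            ok = pg.n_avg > 0
            hits += int((pg.power[ok] > thr[ok]).sum())
            total += int(ok.sum())
        assert hits / total <= 0.04

    def test_high_ar1_clamped_with_warning(self):
        z = hourly_sinusoid(60.0, 365)  # lag-1 autocorr ~ 1
        s = make_series(z)
        with pytest.warns(UserWarning, match="clamp"):
            alpha = cycles.estimate_ar1(s)
        assert alpha == pytest.approx(0.99)


class TestPeaks:
    def test_flat_spectrum_below_threshold_gives_empty(self):
        periods = wavelet.period_grid(3, 60, 12)
        pg = cycles.Periodogram(
            periods_days=periods,
            power=np.ones(len(periods)),
            n_avg=np.full(len(periods), 1000.0),
            rednoise_threshold=np.full(len(periods), 2.0),
        )
        assert cycles.find_significant_peaks(pg) == []

    def test_single_injected_cycle_gives_one_peak(self, default_sim):
        series, _ = default_sim
        s = cycles.preprocess_diea(
            series.timestamps, series.counts, series.visit_dates
        )
        pg = cycles.global_wavelet_spectrum(s)
        cycles.rednoise_threshold(s, pg)
        peaks = cycles.find_significant_peaks(pg)
        assert len(peaks) >= 1
        assert peaks[0][0] == pytest.approx(21.0, rel=0.10)

    def test_quarter_octave_merging(self):
        periods = wavelet.period_grid(3, 60, 24)
        power = np.full(len(periods), 0.1)
        i = 40
        power[i] = 3.0
        power[i + 2] = 2.5  # 2/24 octave away: should merge into i
        pg = cycles.Periodogram(
            periods_days=periods,
            power=power,
            n_avg=np.full(len(periods), 1000.0),
            rednoise_threshold=np.ones(len(periods)),
        )
        peaks = cycles.find_significant_peaks(pg)
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(periods[i])


class TestReconstruction:
    def test_cosine_reconstruction_and_phase_convention(self):
        z = hourly_sinusoid(21.0, 730)
        comp = cycles.reconstruct_cycle(make_series(z), 21.0)
        r = np.corrcoef(z, comp.signal)[0, 1]
        assert r > 0.95
        # phase ~0 at input maxima (excluding edges)
        maxima = np.flatnonzero(
            (z[1:-1] > z[:-2]) & (z[1:-1] >= z[2:])
        ) + 1
        maxima = maxima[(maxima > 500) & (maxima < len(z) - 500)]
        ph = comp.phase[maxima]
        mean_ph = np.angle(np.exp(1j * ph).mean())
        assert abs(mean_ph) < np.pi / 8

    def test_sine_input_quadrature_phase(self):
        t_days = np.arange(730 * 24) / 24.0
        z = np.sin(2 * np.pi * t_days / 21.0)
        comp = cycles.reconstruct_cycle(make_series(z), 21.0)
        # at t=0 a sine sits a quarter cycle before its max: phase -pi/2
        assert abs(
            np.angle(np.exp(1j * (comp.phase[200] -
                     (2 * np.pi * 200 / 24 / 21 - np.pi / 2))))
        ) < np.pi / 8

    def test_noisy_phase_recovery(self):
        from scipy.signal import lfilter

        rng = np.random.default_rng(6)
        t_days = np.arange(730 * 24) / 24.0
        clean = np.cos(2 * np.pi * t_days / 21.0)
        noise = lfilter([1.0], [1.0, -0.8],
                        rng.standard_normal(len(t_days)))
        noise *= clean.std() / noise.std()  # SNR 1
        s = make_series(clean + noise)
        comp = cycles.reconstruct_cycle(s, 21.0)
        true_phase = np.mod(2 * np.pi * t_days / 21.0 + np.pi,
                            2 * np.pi) - np.pi
        # circular correlation of estimated vs true phase
        a = np.sin(comp.phase - np.angle(np.exp(1j * comp.phase).mean()))
        b = np.sin(true_phase - np.angle(np.exp(1j * true_phase).mean()))
        rho = (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())
        assert rho > 0.7


class TestPLV:
    @pytest.mark.parametrize(
        "phases,expected",
        [
            (np.full(5, np.pi / 3), 1.0),
            (np.linspace(0, 2 * np.pi, 9)[:-1], 0.0),
            (np.array([0.0, np.pi / 2]), np.sqrt(2) / 2),
        ],
    )
    def test_analytic_cases(self, phases, expected):
        assert cycles.phase_locking_value(phases) == pytest.approx(
            expected, abs=1e-12
        )

    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=50),
        st.floats(-10, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_rotation_invariance(self, phases, rot):
        plv = cycles.phase_locking_value(phases)
        assert 0.0 <= plv <= 1.0 + 1e-12
        rotated = cycles.phase_locking_value(np.asarray(phases) + rot)
        assert rotated == pytest.approx(plv, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cycles.phase_locking_value([])


class TestPhaseBins:
    @pytest.mark.parametrize(
        "phase,label",
        [
            (0.0, "peak"),
            (np.pi, "trough"),
            (-np.pi, "trough"),
            (-np.pi / 2, "rising"),
            (np.pi / 2, "falling"),
            (np.pi / 4, "falling"),   # half-open boundary
            (-np.pi / 4, "peak"),
            (3 * np.pi / 4, "trough"),
            (-3 * np.pi / 4, "rising"),
        ],
    )
    def test_boundaries(self, phase, label):
        assert cycles.assign_phase_bin(phase) == label

    def test_partition_is_exhaustive_and_equal_width(self):
        grid = np.linspace(-np.pi + 1e-9, np.pi, 40_000)
        labels = cycles.assign_phase_bin(grid)
        counts = pd.Series(labels).value_counts()
        assert set(counts.index) == {"peak", "falling", "trough", "rising"}
        assert (counts / len(grid)).max() - (
            counts / len(grid)
        ).min() < 0.01

    def test_non_finite_phase_rejected(self):
        with pytest.raises(ValueError):
            cycles.assign_phase_bin(np.nan)


class TestOmnibus:
    def test_identical_phases_highly_significant(self):
        p = cycles.omnibus_uniformity_test(np.zeros(20))
        assert p == pytest.approx(20 * 2.0 ** (1 - 20), rel=1e-9)
        assert p < 1e-4

    def test_even_phases_not_significant(self):
        phases = np.linspace(0, 2 * np.pi, 101)[:-1]
        assert cycles.omnibus_uniformity_test(phases) == pytest.approx(1.0)

    def test_power_against_von_mises(self):
        rng = np.random.default_rng(8)
        from scipy.stats import vonmises

        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            ph = vonmises.rvs(1.0, size=100, random_state=rng)
            rejections += cycles.omnibus_uniformity_test(ph) < 0.05
        assert rejections / n_sims > 0.8

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            cycles.omnibus_uniformity_test([0.1, 0.2, 0.3])


class TestCycleSelection:
    def test_no_peaks_raises_exclusion(self, default_sim):
        series, _ = default_sim
        s = cycles.preprocess_diea(
            series.timestamps, series.counts, series.visit_dates
        )
        with pytest.raises(NoMultidienCycleError):
            cycles.select_seizure_locked_cycle(s, [], series.timestamps[:5])

    def test_les_outside_segments_raise(self):
        s = make_series(hourly_sinusoid(21.0, 730))
        far = pd.DatetimeIndex(["2035-01-01"])
        with pytest.raises(InsufficientDataError):
            cycles.select_seizure_locked_cycle(s, [(21.0, 1.0)], far)

    def test_single_peak_returned_regardless_of_plv(self):
        s = make_series(hourly_sinusoid(21.0, 730))
        rng = np.random.default_rng(9)
        le = s.timestamps[rng.integers(0, len(s), 30)]
        comp = cycles.select_seizure_locked_cycle(s, [(21.0, 1.0)], le)
        assert comp.period_days == 21.0

    def test_locked_component_selected(self):
        """LEs locked to the 10-d component of a two-cycle mixture select
        the 10-d reconstruction, across independent event draws."""
        z = hourly_sinusoid(10.0, 730) + hourly_sinusoid(40.0, 730)
        s = make_series(z)
        t_days = np.arange(len(z)) / 24.0
        phase10 = np.mod(2 * np.pi * t_days / 10.0 + np.pi, 2 * np.pi) - np.pi
        rng = np.random.default_rng(10)
        wins = 0
        for _ in range(10):
            # rejection-sample LEs von-Mises locked (kappa=2) to 10-d peak
            idx = rng.integers(0, len(z), 4000)
            keep = rng.uniform(size=4000) < np.exp(
                2.0 * (np.cos(phase10[idx]) - 1)
            )
            le = s.timestamps[idx[keep][:200]]
            comp = cycles.select_seizure_locked_cycle(
                s, [(10.0, 1.0), (40.0, 1.0)], le
            )
            wins += comp.period_days == 10.0
        assert wins >= 9
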