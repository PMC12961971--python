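# multidien

Multi-day ("multidien") cycle analysis for chronic implanted-device EEG
recordings, with a fully parameterised synthetic device-data generator.

## The problem

Implanted responsive-neurostimulation (RNS-class) devices log an hourly
count of detections of interictal epileptiform activity (dIEA). These
counts fluctuate with patient-specific periods of days to weeks, and
seizure-surrogate events ("Long Episodes", LEs) lock to particular phases
of those cycles. The scientific question this package addresses: is the
multidien cycle visible in *background* EEG — band power, within-lead
connectivity, spike rate — recorded in the device's twice-daily 90-s
"Scheduled Event" (SE) clips, and is that relationship attenuated right
after stimulation?

The package implements the full chain for anyone working with long-term
implanted-device data (or wanting a reproducible test bed for multidien
methodology):

1. **Cycle extraction** (`multidien.cycles`) — hourly dIEA counts are
   regularised, z-scored between clinic visits, and transformed with a
   complex Morlet continuous wavelet transform (ω₀ = 6). The time-averaged
   wavelet power over periods 3–60 d is tested against the 99% level of an
   AR(1) "red-noise" null, P(f) · χ²ᵥ/ν with
   ν = 2·√(1 + (n·δt/γs)²); each significant peak is reconstructed by a
   band-limited inverse transform (±⅓ octave) and given an instantaneous
   phase by the Hilbert transform. The component most phase-locked to LE
   times — largest phase-locking value, PLV = |n⁻¹ Σₖ e^{iφₖ}| — is the
   patient's cycle; LE non-uniformity is tested with the Hodges–Ajne
   omnibus test.
2. **EEG features** (`multidien.features`) — per SE clip (or per 10-s
   window starting 2 s after a stimulation): Welch band power in theta
   (4–8 Hz), alpha (8–13), beta (13–30) and gamma (33–100, 60±2 Hz
   excluded), max over the two detection channels; normalised
   cross-wavelet connectivity within each lead, max over leads; a day/night
   covariate (08:00–20:00); and a morphology-gated robust-amplitude spike
   rate. Features are log-transformed (powers) and z-scored between
   clinic visits.
3. **Phase classification** (`multidien.classify`) — within-patient
   standardize → PCA (95% variance) → linear SVM, 10-fold stratified CV
   AUROC for peak-vs-trough (PvT), rising-vs-falling (RvF), PvR, RvT and a
   four-class model; significance by 1000 label permutations
   (p = (1 + #{null ≥ obs})/(n+1)); feature importances by inverse-PCA
   back-projection of the SVM weights.
4. **Statistics** (`multidien.stats`) — exact two-tailed sign test,
   pooled-SD Cohen's d, one-way ANOVA over phase bins, Kruskal–Wallis,
   χ² goodness of fit, rank-sum, Spearman/Pearson.
5. **Synthetic device data** (`multidien.synthetic`) — Poisson dIEA counts
   with log-linear multidien + circadian + AR(1) modulation; von-Mises
   phase-locked LEs; SE catalogs with phase-biased dropout and
   stimulation; 4-channel EEG clips (1/f background, phase-modulated
   band oscillations and within-lead coherence, injected biphasic spikes,
   stimulation artifacts). Every stream is seeded and ships its ground
   truth, so each stage has a parameter-recovery test surface.

Real patient data of this kind cannot be redistributed; a transcription of
the published per-patient cohort table (20 patients: LE PLV, cycle period,
device rates, …) ships as a packaged fixture (`multidien.io.load_table1`).

## Worked example

```python
import numpy as np
from multidien import cycles, synthetic

cfg = synthetic.SimulationConfig(seed=1)          # 21-day cycle, 2 years
series, truth = synthetic.simulate_diea(cfg)      # hourly Poisson counts
le_times = synthetic.simulate_les(truth, cfg)     # phase-locked seizures

s = cycles.preprocess_diea(series.timestamps, series.counts,
                           series.visit_dates)
pg = cycles.global_wavelet_spectrum(s)
cycles.rednoise_threshold(s, pg)                  # 99% AR(1) level
peaks = cycles.find_significant_peaks(pg)
comp = cycles.select_seizure_locked_cycle(s, peaks, le_times)
print(f"selected {comp.period_days:.2f}-day cycle, "
      f"PLV {comp.plv:.3f} over {len(le_times)} LEs")
```

prints

```
selected 20.77-day cycle, PLV 0.491 over 218 LEs
```

— the injected 21-day cycle recovered within 1.1%, and an LE
phase-locking value of 0.49 against the von-Mises closed form
I₁(1)/I₀(1) ≈ 0.446 at the configured concentration κ = 1.

The same chain runs from the shell:

```bash
multidien simulate --out data/ --seed 1
multidien cycles --diea data/diea.csv --visits data/visits.csv \
    --events data/events.csv --out results/
multidien report --out cohort.json   # packaged fixture summary
```

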