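# Methods

This note documents the models, conventions and numerical choices behind
`multidien`, and what the synthetic-data tests do and do not demonstrate.

## dIEA preprocessing

Hourly detection counts are placed on a strict hourly grid. Gaps of at
most 24 h are linearly interpolated and flagged; longer gaps split the
record, and segments shorter than 90 days are discarded (a record must
cover several cycle periods for the periodogram to be meaningful). The
first 28 days are dropped to avoid the post-implant stabilisation
transient. Counts are z-scored within clinic-visit intervals
(intersected with data segments): device detection parameters are
retuned at visits, so between-visit standardisation removes step changes
and slow drifts. Zero-variance blocks map to z = 0. The order is
interpolate → z-score.

## Wavelet periodogram and red-noise significance

The multidien periodogram is the time-averaged power of a complex Morlet
(ω₀ = 6) continuous wavelet transform of the z-scored counts, evaluated
on a log-spaced period grid (3–60 days, 24 voices per octave). The CWT is
computed in the frequency domain with the scale normalisation under which
the expected wavelet power of a stationary process equals its Fourier
spectrum; this is what makes an analytic null distribution available.
Samples inside the cone of influence (distance to an edge less than the
e-folding time √2·s) are excluded from the average, and within a segment
periods longer than half the segment are masked. Multi-segment records
average segment spectra weighted by the number of contributing samples.

Significance is assessed against an AR(1) ("red noise") null: the lag-1
autocorrelation α̂ of the z-scored series parameterises
P(f) = (1−α̂²)/(1+α̂²−2α̂·cos 2πfδt), scaled by the series variance, and
the 99% threshold is P(f)·χ²ᵥ,₀.₉₉/ν with the effective degrees of
freedom of time-averaged wavelet power, ν = 2·√(1+(nₐδt/γs)²), γ = 2.32
for Morlet(6). α̂ ≥ 0.99 is clamped with a warning. Monte-Carlo
calibration on pure AR(1) input (α = 0.8, 730 days, 200 replicates)
gives a pooled exceedance rate of ≈1.9% at the 99% level — the mild
excess is expected because α̂ is estimated per replicate rather than
known. Note that the *threshold* is not flat even for white noise: the
AR(1) spectrum is flat at α = 0, but ν falls with scale, so the χ²
factor grows toward long periods by design.

Peaks are local maxima of power strictly above the threshold (grid
interior only); maxima within ¼ octave merge, keeping the higher. An
empty peak list is a valid outcome and downstream selection raises the
"no multidien cycle" exclusion error.

## Cycle reconstruction, phase and PLV

Each candidate peak is reconstructed by the band-limited inverse
transform over scales within ±⅓ octave of the peak period (wide enough to
tolerate period drift, narrow enough to isolate the mode), mean-removed,
and given an instantaneous phase by the Hilbert transform per segment.
Convention: phase 0 at local maxima of the component, −π/2 on the rising
flank, ±π at the trough. Phase bins are the quadrants: peak
[−π/4, π/4), falling [π/4, 3π/4), trough [3π/4, π] ∪ (−π, −3π/4),
rising [−3π/4, −π/4), half-open at the upper edge.

Events (LEs, SE clips) take the phase of the nearest hourly sample — the
native resolution of the count stream — and events outside analysis
segments get no phase. The seizure-locked component is the candidate
with the largest LE phase-locking value PLV = |n⁻¹Σe^{iφ}|; ties break
toward the shorter period (locking is empirically stronger in shorter
cycles). LE non-uniformity uses the Hodges–Ajne omnibus statistic m
(minimum count in a closed half-circle) with the exact tail
p = (n−2m)·C(n,m)·2^{1−n} in its validity region m < n/3; for m ≥ n/3
the distribution is practically uniform and p is reported as 1.

## EEG features

Band power: Welch estimate with 1-s Hamming windows, 50% overlap; mean
power density over the band; 60 ± 2 Hz excluded from gamma (mains);
maximum over the two detection channels; log₁₀ before z-scoring (power is
right-skewed). Bands: theta 4–8, alpha 8–13, beta 13–30, gamma
33–100 Hz (the 250-Hz device bandwidth caps gamma below Nyquist).

Connectivity: within each lead, the Morlet CWTs of the two channels are
combined per 1-s non-overlapping window as
|ΣWₐW_b*| / √(Σ|Wₐ|²·Σ|W_b|²) over samples × scales (6 voices/octave);
the lead value is the window mean and the feature is the max over leads.
The normalised (coherence-like) form is used so the max over leads is
scale-fair; unnormalised cross-power would conflate power with coupling.
The null level of this statistic depends on the per-window degrees of
freedom and therefore on band frequency: Monte-Carlo levels on
independent noise are ≈0.5 (theta), ≈0.34 (alpha), ≈0.19 (gamma). Tests
assert these derived levels rather than a single band-independent bound.

Spike detector: per channel, band-pass 1–35 Hz (4th-order Butterworth,
zero-phase), robust z via median/MAD; candidates are local extrema with
|z| > 6 whose event duration lies in 20–200 ms and whose second-difference
sharpness exceeds robust z = 2; events within 200 ms across channels
merge. Event duration is measured near the lobe base (width at 10% of
peak prominence), matching the clinical total-duration convention for
spikes and sharp waves — a half-amplitude measurement would reject the
canonical 30-ms sharp lobe that the width gate is meant to accept.
Samples within ±1 s of a stimulation offset are masked (artifact
transients mimic spikes), and clips with >20% of samples at the
amplifier rail are rejected. On synthetic clips the detector operates at
≈96% recall (±50 ms) for 8-SD templates with ≈0 false detections per
spike-free clip; this validates internal consistency with the generator,
not clinical performance.

Post-stimulation analysis windows span [t+2 s, t+12 s] after each
stimulation at t; windows that run past the clip end or contain a later
stimulation's artifact are discarded (conservative overlap rule). The
day/night covariate is 1 in [08:00, 20:00) local time. Feature rows are
z-scored within clinic-visit segments (the binary day/night flag is left
untouched); segments with fewer than 10 rows are flagged and excluded
from modeling. A dataset must contain at least 200 analysis windows
(inclusion criterion); smaller datasets fail validation.

## Phase classification

Per patient and contrast: standardize → PCA retaining 95% variance
(multicollinearity control) → linear SVM (hinge loss, C = 1, balanced
class weights — phase-dependent clip availability makes classes
imbalanced), 10-fold stratified CV, AUROC from decision values
(no calibration step), mean over folds; the four-class model reports
macro one-vs-rest AUROC. Standardisation and PCA are fit inside each
training fold. Significance: labels permuted within the patient's table,
identical protocol per permutation, one-sided
p = (1+#{null ≥ obs})/(n_perm+1) (the +1 avoids p = 0). Because the
scaler and PCA are label-independent and folds are fixed, their per-fold
fits are reused across permutations — numerically identical to a full
refit. Feature importances: SVM weights mapped through the PCA loading
transpose and divided by training standard deviations; positive = higher
at the positive class (peak, or rising for RvF/RvT).

AUROC inside the CV loop is computed by the rank (Mann–Whitney)
identity; tests cross-check it against scikit-learn's implementation.

## Synthetic device data

The generator is a test harness, not a biological claim. Defaults
emulate the published device context: 2-year records, hourly counts with
mean rate 50/h (device rates span ≈19–92/h), a 21-day multidien cycle of
log-depth 0.5, circadian log-depth 0.3, AR(1) log-noise (α = 0.8,
stationary SD 0.25 — a scale parameter the count model needs but no
published source specifies), Poisson sampling, clinic visits every 90
days. LEs arrive at 0.3–0.4/day with von-Mises phase locking (default
κ = 1, mean at the rising phase −π/2). SEs occur at 10:00/22:00; dropout
and stimulation probabilities are logistic with bias terms
(σ(−1.5 + 1.0·cos φ) for dropout — low-priority clips are overwritten
when the device is busy near cycle peaks; zero gain disables the
mechanism entirely so that unbiased catalogs are exactly complete).

Clips are 90 s, 4 channels (two per lead), 250 Hz: 1/f background
(10 µV RMS), band oscillations at 6/10/20/60 Hz with amplitude
A_b(1+g_b cos φ) (g = 0.4/0.5/0.4/0.3) mixed with a shared per-lead
component at coherence 0.4 + 0.2·cos φ, biphasic spikes (30-ms sharp
negative + 40-ms slow positive lobes, 8× the composite background's
robust SD) at rate 1/min · e^{0.5·cos φ}, a ±20% day/night amplitude
factor, and 100-ms 100-Hz artifact bursts at stimulation offsets.
Between-clip variability — the dominant feature of real EEG that keeps
classifiers off ceiling — is modelled as log-normal amplitude jitter
(SD 0.5 shared across bands, 0.3 per band) plus coherence jitter
(SD 0.15). Stimulated clips carry modulation gains attenuated by a
factor 0.5, the simulated post-stimulation suppression of the
cycle-EEG relationship.

What the generator does *not* emulate: sleep architecture, seizure
dynamics within clips, electrode drift, detector retuning inside visit
intervals, inter-channel propagation delays, or realistic spike
morphology variability. Passing tests therefore demonstrate that the
pipeline recovers what it is designed to recover under its own model
class — not clinical validity on patient data.

## Problem sizes of the verification runs

Chosen so the full suite runs comfortably on a single CPU:

* red-noise calibration: 200 AR(1) replicates of 730 days;
* parameter recovery: one default 2-year simulation; LE sets at κ = 1, 2;
* classifier calibration: 20 null tables (n = 400); permutation-p
  uniformity over 40 replicate tests at 99 permutations (KS at α = 0.01);
  power at Cohen's d = 0.8 with 200 permutations (the library default
  stays at 1000);
* synthetic cohort: 8 patients, 365-day records, ≈210 analysis clips per
  dataset kind (above the 200-clip inclusion floor), cycle periods drawn
  from 8–32 days, κ from 1.5–2.5. Eight patients make the cohort sign
  test usable (7–8 consistent patients reach p < 0.05).

## Known limitations

* The Hodges–Ajne p-value is exact only for m < n/3; above that the
  conservative value 1.0 is returned.
* The EDF codec writes plain 16-bit EDF with 1-s records and integer
  sampling rates only; it exists because the clip container format
  needs a writer, and is cross-checked against an independent reader.
* The four-class classifier reports macro one-vs-rest AUROC from
  decision values; no probability calibration is attempted.
* `run_pipeline` operates on simulated cohorts; device data enter
  through the step-wise CLI (`cycles`, `features`, `classify`) instead.
* No multiple-comparison correction anywhere: the analyses are
  exploratory by design, and the sign-test tables should be read
  accordingly.
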