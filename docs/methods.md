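# Methods

This note documents the models, numerical choices and limitations behind
`ushrv`, in the spirit of a statistical package's methods appendix.

## Data model

An RR series is a vector of strictly positive inter-beat intervals in
milliseconds.  Time starts at the first detected beat; `beat_times[i]`, the
cumulative interval sum in seconds, is the time of the beat *terminating*
interval *i*.  Only relative timing matters for every statistic computed
here, so no absolute clock is kept.  File I/O uses fixed `%.3f` formatting,
making round trips exact to 1 µs-scale resolution in ms and output
byte-stable.

## Preprocessing

**Artefact detection.**  Interval *i* is flagged when it deviates from the
median of its `median_window` (default 11) nearest neighbours — excluding
itself — by more than the sensitivity threshold: 0.45/0.35/0.25/0.15/0.05 s
for very-low through very-strong, with *strong* (0.15 s) the default.  This
deviation-from-local-median rule with that threshold ladder is the widely
reported behaviour of commercial HRV software; the exact proprietary
algorithms are unpublished, so this is an explicit design choice of the
package.

**Correction.**  Flagged intervals are replaced by a cubic spline fitted to
unflagged intervals in beat-index space, preserving the beat count.  Beats
flagged before the first (or after the last) clean beat take the nearest
clean value: cubic extrapolation at the edges can produce wildly
non-physiological (even negative) intervals, so it is deliberately not
used.  When fewer than four clean beats remain, replacement falls back to
linear interpolation; an entirely flagged series is an error.

**Detrending.**  The smoothness-priors trend solves
(I + λ²D₂ᵀD₂)·trend = z with D₂ the (N−2)×N second-difference matrix, and
the stationary series is z − trend + mean(z); restoring the mean keeps
time-domain metrics in ms around the physiological level.  λ defaults to
500, the conventional setting for short-term HRV (acting as a high-pass
with a cutoff in the VLF range at typical beat rates).  The system is
symmetric positive-definite and pentadiagonal; it is solved with a banded
Cholesky routine (O(N), comfortably under a second at N = 10⁴), with a
dense fallback below N = 6 where the band structure degenerates.  λ = 0
reduces the output to the constant mean series; an exactly constant input
is returned unchanged (its trend is itself, exactly, which a finite-
precision solve would only approximate).  Detrending never increases
variance.

Preprocessing is applied per analysis window, after extraction, and the
time-domain metrics are computed on the detrended, mean-restored series —
matching how mainstream HRV software behaves when smoothness priors are
enabled.  Whether detection should instead run once on the full recording
is a defensible alternative; per-window processing was chosen so that every
window's result depends only on its own data.

## Metrics

SDNN uses the sample (N−1) standard deviation; RMSSD averages the N−1
squared successive differences; pNN50 counts differences *strictly* above
50 ms and divides by N−1 (the conventional denominator, even though the
name suggests dividing by the interval count).  These conventions are
pinned so that toy examples are exactly reproducible.

For the spectrum, the unevenly sampled tachogram (beat time, interval) is
cubic-spline interpolated to a uniform 4 Hz grid — the de-facto standard
resampling rate — and the mean is removed.  The PSD is a one-sided Welch
estimate: Hann window, segment length min(N, 256) samples (64 s at 4 Hz),
50 % overlap, linear detrend per segment; windows shorter than 64 s thus
use a single full-length Hann periodogram.  These parameters resolve the
0.04 Hz VLF/LF boundary on windows of a minute or more while limiting
estimator variance.  Band powers are trapezoidal integrals over the
half-open bands VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4) Hz, with
the PSD linearly interpolated at the exact band edges so adjacent bands
partition the spectrum.  **Total power is defined as VLF + LF + HF**, so
the normalised powers nX = X/total × 100 always lie on a 100-nu simplex.
(Note this normalisation differs from the Task-Force convention
LF/(total − VLF); the simplex definition is the one used throughout this
package.)  Zero total power — e.g. a constant series — leaves the
normalised powers undefined (NaN, flagged `spectral_undefined`), never 0.
Windows under 30 intervals are flagged `low_confidence`.

## Segmentation

Nine windows: five consecutive 1-minute windows, cumulative 0–2/0–3/0–4
windows, and the 0–5-minute standard.  Membership is by terminating-beat
time in the half-open window (start, end], which makes the five 1-minute
windows an exact partition of the standard window — no interval lost or
double-counted.  Recordings more than 2 s short of a window's end are
logged.

## Agreement battery

* **Cohen's d** uses the pooled-SD standardiser
  s_p = √((s_x² + s_y²)/2) — not the difference-score SD — with the
  large-sample CI d ± 1.96·√(2/n + d²/(4n)).  With zero pooled SD, d is 0
  when the means agree and undefined otherwise.
* **ICC(2,1)**: two-way random effects, single measure, absolute agreement,
  (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) from the ANOVA mean
  squares.  Absolute agreement (not consistency) is the right variant for
  interchangeability questions, since a constant offset between devices
  should be penalised.  Zero total variance → undefined.
* **Spearman's ρ** via average-tie ranks (scipy); degenerate rank variance
  → undefined.
* **Bland–Altman**: bias = mean(x − y), limits = bias ± 1.96·SD (sample
  SD); the per-subject (mean, difference) cloud is retained for export and
  plotting.  No proportional-bias regression is fitted.
* **Paired-t power** uses the noncentral t distribution with df = n − 1 and
  noncentrality dz·√n, two-sided.

Magnitude labels follow the conventional sports-science scales.  Printed
scales leave small gaps (e.g. an ICC of 0.695 between "moderate ≤ 0.49"
and "large ≥ 0.50" style bins); all boundary and gap values resolve to the
**lower** class, and labels are taken on the absolute value.  No
multiple-testing correction is applied — the battery is descriptive.

## Synthetic cohort

Each subject's tachogram is RR(t) = rr0 + Σ_b a_b sin(2π f_b t + φ_b) + ε,
sampled at the beats it generates (the modulation is evaluated at each
interval's terminating beat, where the tachogram places it, via one
fixed-point refinement).  A sinusoidal model was chosen over
integral-pulse-frequency modulation because each component's tachogram
power is a_b²/2 in closed form, giving exact oracles for the spectral
pipeline; IPFM realism is a possible extension.  Cohort defaults describe
young healthy adults seated at rest: rr0 ~ N(850, 70²) ms (clipped to
600–1100), log-normal amplitudes with medians 18/22/28 ms and log-SDs
0.4/0.4/0.5 for VLF/LF/HF (the wider HF spread mimicking between-subject
variation in respiratory sinus arrhythmia), frequencies uniform in
0.005–0.035 / 0.06–0.13 / 0.18–0.35 Hz (HF = 11–21 breaths/min,
spontaneous breathing), white noise U(8, 18) ms, amplitudes capped at
70 ms so intervals stay positive.

The test device degrades *beat times*, not intervals: N(0, 3² ms) jitter,
0.5 % missed beats (adjacent intervals merge into a long outlier) and
0.5 % spurious beats (an interval splits uniformly), so artefacts arise
the way chest-strap transmission glitches actually present.  Per-subject
seeds derive as master_seed + index, so any subject is reproducible
independently of cohort size.

What the generator does **not** emulate: non-stationarity within a
recording (each subject's oscillation parameters are fixed, so segment-
vs-standard disagreement here reflects estimation noise only, not the
orthostatic drift real stabilisation data may contain), broadband "1/f"
VLF structure, respiratory amplitude modulation, or posture/circadian
effects.  Passing tests therefore demonstrate that the *pipeline* behaves
correctly under controlled conditions, not that any particular device is
valid on real data.

## Problem sizes and determinism

The simulation-based checks use 60-subject cohorts of 5-minute recordings
(≈ 360 beats each) and, for the qualitative-pattern check, 30 seeded
cohorts — sizes at which the whole battery runs in about a minute on one
core while keeping Monte-Carlo noise well below the asserted margins.  All
randomness flows through explicit integer seeds (numpy `default_rng`);
every table, file and statistic is bit-reproducible for a fixed seed and
configuration.

## Known limitations

* The artefact rule is a reconstruction of common practice, not a vendor
  algorithm; beat counts are preserved (no beat re-detection), so a missed
  beat is repaired as one long interval rather than re-split.
* Normalised powers use the in-package total-power definition above;
  comparisons with Task-Force-normalised nLF/nHF values require
  conversion.
* CIs are reported for Cohen's d only; ICC and ρ are point estimates.
* Ultra-short windows (1 min) resolve the VLF band poorly by construction
  (only ~2.4 cycles of a 0.04 Hz component fit); nVLF on such windows is
  reported but inherently noisy, which is precisely the phenomenon the
  nine-window design is meant to expose.
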