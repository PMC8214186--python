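# Methods

This note documents the models, numerical choices and limitations behind
each estimator, and what the synthetic-data generators do and do not
emulate.

## Camera-PPG heart-rate estimation

### Signal model

The input is the per-frame mean pixel intensity of each color channel of a
flash-illuminated fingertip video, nominally at 60 Hz. The blood-volume
pulse appears as a quasi-periodic modulation riding on a large DC level,
with slow baseline drift (perfusion and pressure changes) and broadband
sensor noise. The estimator assumes the pulse is approximately periodic
within a 10-second analysis window.

### Pipeline and parameters

1. **Resampling** — linear interpolation onto a uniform grid at the nominal
   rate. Camera timestamps jitter by milliseconds; linear interpolation is
   adequate because the pulse band (≤ 3.5 Hz) is far below Nyquist.
2. **Band-pass** — zero-phase Butterworth, order 4, 0.6–4.0 Hz, applied
   forward-backward, then mean-centering. The band covers the 45–210 bpm
   (0.75–3.5 Hz) search range with margin on both sides; zero-phase
   filtering preserves peak locations.
3. **Windowing** — consecutive non-overlapping 10 s windows; a trailing
   partial window is discarded. 10 s is the shortest window holding several
   beats at 45 bpm.
4. **Period estimation** — biased (divide-by-N) autocorrelation, computed
   by FFT and normalized by the lag-0 value. The biased estimator tapers
   long lags by (1 − k/N), which mildly favors the fundamental over
   subharmonics and keeps the normalized values bounded by 1. Candidate
   peaks are local maxima whose lag lies in the physiological band and
   whose magnitude is at least `peak_threshold` (default 0.25) of the lag-0
   peak; the strongest candidate is the fundamental.
5. **Sub-sample refinement** — quadratic (three-point parabolic)
   interpolation around the integer peak lag, clipped to ±0.5 samples. At
   60 Hz a one-sample lag error near 210 bpm corresponds to >10 bpm, so
   integer lags cannot meet a ±1 bpm accuracy target at the top of the
   range; refinement reduces the error to well under 1 bpm across the whole
   range. The refined HR is clipped to [hr_min, hr_max].
6. **Lag search band** — `[max(1, floor(60·f_s/hr_max)), ceil(60·f_s/hr_min)]`.
   Floor on the short-lag side keeps the period of `hr_max` inside the band
   when it is not an integer number of samples (210 bpm at 60 Hz is 17.14
   samples); the subsequent clipping guarantees estimates never leave the
   physiological range.
7. **Confidence** — the normalized ACF magnitude at the fundamental lag,
   clipped to [0, 1]; 0 when no candidate survives. It is scale-free
   (amplitude-invariant) and decreases with noise, which makes a fixed
   cutoff meaningful across devices. The default QC cutoff is 0.5. An
   alternative diagnostic, the ratio of the fundamental peak to the next
   candidate peak (`AcfResult.peak_ratio`, ≥ 1, unbounded), is exposed but
   not used for QC: the two definitions are genuinely different quality
   notions, and only the bounded one composes with a [0, 1] cutoff.
8. **Channel fusion** — red and green are estimated independently and the
   higher-confidence channel wins; exact ties go to green, where hemoglobin
   absorption (and hence pulsatile contrast) is strongest. Blue is parsed
   and reported but never fused.

A window with no surviving candidate yields confidence 0 and no HR rather
than an error, so long captures degrade gracefully; a 20-s resting capture
is aggregated as the mean of its valid windows.

### Verified behavior

On clean synthetic pulses the estimator recovers every rate from 45 to
210 bpm with median absolute error ≈ 0.1 bpm and worst-case < 0.3 bpm; its
fundamental frequency agrees with a band-restricted periodogram argmax
within one frequency bin on noisy windows (noise SD 2 against pulse
amplitude 10, ≈ 11 dB SNR); pure-noise windows are rejected at cutoff 0.5
in ≥ 95% of replicates. These figures are recomputed by the test suite.

## VO₂max estimation

Both prediction equations are affine and live in configuration objects
carrying a mandatory source string:

* Step test (Milligan's Tecumseh-family regression):
  `83.477 − 0.586·HB3060 − 0.404·age − 7.030·sex`, sex coded 0 male /
  1 female. HB3060 outside 22.5–105 beats (45–210 bpm sustained over half a
  minute) triggers a warning.
* Run test (Cooper): `(d12 − 504.9) / 44.73`, d12 in meters; distances
  outside 500–6000 m warn, which catches kilometers-vs-meters confusions.

HB3060 is derived from the windowed HR estimates as the overlap-weighted
mean of the valid fused HR over [test_end+30, test_end+60], times 0.5 min —
overlap weighting because the 10-s analysis grid does not align with the
counting interval. Rounding to one decimal happens only at presentation.

## GPS distance

Displacement records are accumulated into a planar path; degrees-dialect
records are first integrated from the anchor and then projected with a
local equirectangular projection (x = R·Δλ·cosφ₀, y = R·Δφ, R = 6 371 000 m).
The projection error is below 0.1% for tracks spanning less than ~5 km,
which both test protocols satisfy; the meters and degrees encodings of the
same trajectory agree to that tolerance.

Raw distance sums Euclidean segment lengths and is biased upward under
position jitter (each segment adds |noise| in expectation). The smoothed
estimator applies a Savitzky-Golay filter (window 9 samples = 9 s at 1 Hz,
polyorder 3) to each coordinate before summation. Edge handling uses
polynomial fitting (`mode="interp"`): a noiseless locally-polynomial
trajectory is then reproduced exactly, so the smoothed distance equals the
raw distance in the noiseless limit — mirror padding would fold a ramp back
at the edges and break that property. Paths shorter than the window fall
back to raw with a warning. Per-sample steps above 15 m (faster than a
world-record sprint at 1 Hz) are flagged, not dropped.

## Individual typology angle

`ITA = arctan((L* − 50)/b*)·180/3.14159`. The 180/3.14159 constant is kept
verbatim by default so results match the conventional arithmetic
digit-for-digit (the difference to true π is < 0.001° and never moves a
category); `exact_pi=True` switches to π. For b* ≤ 0 (possible on
instrument noise) the two-argument arctangent resolves the angle toward
±90° by the sign of L* − 50, with a warning. Category boundaries use the
chain 55/41/28/10/−30 degrees with the cutoff value itself assigned to the
darker-adjacent category (the chain is written with strict inequalities on
both sides, which leaves exact boundary values unassigned; some convention
is required and this one is configurable).

## Agreement statistics

* Lin's ρ_c uses population (1/n) moments as in the original formulation;
  a flag switches to n−1 moments. ρ_c is symmetric, bounded by |Pearson r|,
  and invariant under a common affine rescaling of both vectors.
* Bland-Altman: bias = mean(test − reference), limits = bias ± 1.96 × sample
  SD (n−1).
* Percent error is absolute by default (100·|test − ref|/ref); a signed
  variant exists. Zero-reference pairs are excluded with a warning.
* ICC: single-measure, two-way, absolute-agreement — ICC(2,1) from the
  mean-squares decomposition — chosen as the standard test-retest form;
  the variant name is printed in every report because different ICC forms
  are not comparable. Subjects with missing repeats are dropped listwise.
* Retention curve: fraction of windows with confidence ≥ cutoff, per
  cutoff; monotone non-increasing by construction.

## Synthetic-data generators

All generators are pure functions of their spec including the seed.

* **PPG** — a phase-continuous oscillator integrates the instantaneous HR
  profile (constant, or mono-exponential recovery
  `asymptote + (start − asymptote)·e^(−t/τ)` — a modeling choice for test
  ground truth, not a physiological claim); the default pulse shape is
  harmonic-rich (fundamental + 0.4× second harmonic) because harmonic
  rejection is the hard case for ACF fundamental selection. Channel gains,
  additive white noise, sinusoidal baseline drift and a 0–255-like offset
  complete the model. Ground truth is the per-window mean of the
  instantaneous HR. Not emulated: motion artifacts, saturation/clipping,
  frame drops, ambient-light leakage, and the optics of real skin — so
  passing tests demonstrate correctness of the signal-processing chain
  under the stated signal model, not field robustness.
* **GPS tracks** — positions at 1 Hz along a line, circle or waypoint
  polyline, iid Gaussian jitter per position, differenced into either
  dialect. Real GPS errors are temporally correlated and heavier-tailed
  than iid Gaussian; the smoothing benefit measured here is therefore an
  idealized-case result.
* **Agreement cohorts** — value = mean + subject effect + bias + noise,
  with the implied ICC = σ²_subject/(σ²_subject + σ²_error) returned as
  ground truth.

## Problem sizes

Default test and acceptance runs use 10–90 s captures at 60 Hz (600–5400
samples), 200-replicate Monte-Carlo loops for stochastic claims, 720-sample
tracks, and 500-subject cohorts — sizes at which every stated tolerance has
comfortable margin while the whole suite runs in seconds.

## Known limitations

* The confidence score is a periodicity measure, not an accuracy bound: a
  strongly periodic artifact (e.g. rhythmic finger motion) would pass QC.
* The equirectangular projection degrades near the poles and for tracks
  spanning many kilometers.
* The VO₂max regressions are transcriptions of published equations; no
  refitting against gold-standard measurement is attempted, and their
  population validity is inherited from their sources.
* ICC is returned as a point estimate without confidence intervals.
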