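# Methods

## Problem and signal model

A dual-wavelength polarization-sensitive optical sensor records flying
insects crossing a continuous-wave laser beam on three channels: intensity at
924 nm (NIR), and the co- and cross-polarized intensities at 1320 nm (SWIR).
Each transit ("event") is the product of a position coefficient ρ(t) — the
ratio of the beam power density at the insect's position to the on-axis
maximum — and the insect's effective optical cross sections. The body
contributes a slowly varying return; the wings add a train of sharp flashes
at the wingbeat frequency (WBF). Because the body of a gravid female scatters
with a higher linear depolarization ratio (δ_b ≈ 0.62 vs 0.45) and the WBF
rises ≈5% under the egg load, these features support a gravidity classifier.

### Transit envelope

The beam has a Gaussian profile with 25.4 mm FWHM. A straight transit at
transverse speed v gives ρ(t) = ρ_peak · exp(−4 ln 2 · t²/T²) with
T = FWHM / v. Default ρ_peak = 1 (center transit): the calibrated magnitudes
then equal the true cross sections at the peak, and since all channels share
the beam, ρ cancels in every ratio feature, so off-axis transits only rescale
magnitudes. Events are simulated over ±1.25 T, giving edge amplitudes ≈1% of
peak.

### Wing flashes

The flash waveform is a half-wave-rectified harmonic comb:
rect(Σ_h a^{h−1} cos(h·u)) normalized to unit peak, with u the wingbeat phase,
`n_harmonics` = 4 and per-harmonic decay a = 0.6 by default. This choice (the
true waveform is not specified by any source we model) produces a spectrum
with a fundamental plus decaying harmonics and — critically for the
decomposition — returns exactly to zero between beats, which is what lets a
sliding minimum recover the body level. Because all cosines align at u = 0
(mod 2π), the wing peak equals the wing cross section when a flash falls near
the beam center; with ≈30 flashes per transit the nearest flash sits within
half a period of center and the resulting amplitude deficit is < 0.1%.

### Channels, noise, bandwidth

The six component cross sections are tied per event by
σ_⊥ = δ·σ_∥ (body and wing separately) and σ_924 = σ_1320∥ / r, where r is
the SWIR/NIR cross-section ratio (body default 2.5, wing 1.6). A single-pole
low-pass at the 67 kHz detector bandwidth is applied (nearly transparent at
mosquito harmonics given the 30 517 Hz sampling), then additive white
Gaussian noise per channel (default sd 0.005 mm²-equivalent, i.e. a
high-SNR short-range laboratory measurement; no documented noise figure
exists for the modeled instrument). Traces are not clipped at zero by
default so linearity holds exactly in tests.

### Class-conditional dispersions

Printed class means fix the centers (δ_b 0.45/0.62, WBF 347/365 Hz,
SWIR/NIR 2.5 body / 1.6 wing); within-class spreads are free parameters
chosen once for biological plausibility: WBF sd 30 Hz, δ_b sd 0.08, δ_w sd
0.05, cross-section magnitudes 15% relative sd, SWIR/NIR ratio sds 0.2
(body) and 0.15 (wing), transit speed 0.3 ± 0.05 m/s. Dispersion on the
optical ratios is deliberate: individual insects differ in melanization and
water content, and without it within-class feature variance would be
extraction noise only. All are config values, not constants.

The simulator does **not** model: multiple insects per transit, clutter
(rain/dust), range-resolved returns, curved or re-entrant trajectories,
within-transit orientation drift of the body spectral ratio, or non-Gaussian
detector noise. Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical model, not field performance.

## Decomposition

Per channel, the body estimate is: short moving average (0.3 ms) → sliding
minimum over `window_s` (default 5 ms, ≥ one wing period for WBF ≥ 200 Hz) →
moving average over `window_s`. The wing series is the remainder, so
body + wing reconstructs the input exactly. The 0.3 ms pre-average exists
because a raw sliding minimum under additive noise is biased low by the
expected extreme deviate (≈ 2.5 sd over a 5 ms window), which would distort
body cross-section *ratios*; averaging ~9 samples first cuts that bias an
order of magnitude while staying far below the ~1.4 ms flash width. In the
noiseless limit the estimator is scale-equivariant and identical across
channels, so ratio features are exact there.

Cross sections: wing σ = channel gain × max of the zero-floored wing series
(the brightest flash); body σ = gain × max of the smoothed envelope; both
divided by `rho_assumed` (default 1). Whether the body should use a
transit-average instead of the maximum is genuinely open; the maximum is
used, and only ratios feed the classifier so the choice cancels there.
Cross-polarized components are additionally scaled by the calibration
constant G.

## Calibration

Gains come from a Lambertian target of known cross section:
gain_c = σ_target / mean(trace_c) for the 924 and 1320∥ channels. The 1320⊥
channel inherits the parallel gain, and the polarization cross-calibration
constant G = (true ⊥/∥ ratio of the reference) × mean(I_∥)/mean(I_⊥) carries
all relative correction, so δ = G·I_⊥/I_∥ computed on raw intensities equals
the calibrated cross-section ratio by construction.

## Feature set

18 predictors per event, in fixed column order: the natural logs of all 15
unordered pairwise ratios of the six cross sections (components ordered so
that the body and wing depolarization pairs read ln δ_b and ln δ_w
directly), then WBF and the power of the 2nd and 3rd comb teeth relative to
the fundamental. Logs are used for symmetry (swapping a pair negates the
feature) and to make multiplicative noise additive for the linear
classifier; the transform is monotone and reversible. Which exact 18
predictors the motivating study used is not enumerable from its text; this
set follows its description (all cross-section ratio combinations + WBF +
harmonic content) and is isolated behind `FEATURE_NAMES` so alternatives
can be swapped in.

WBF estimation: Welch periodogram (Hann, segments ≤ 1024 samples, 50%
overlap, 4× zero padding), then the candidate in [150, 900] Hz maximizing
the comb score P(f) + P(2f) + P(3f), which rejects octave errors. If the
winning candidate's own bin does not exceed 5× the in-band median power the
candidate is promoted by octaves (a near-pure tone ties the comb score at
its empty half-frequency subharmonic); if no bin clears the floor the event
is flagged "no WBF detected" and dropped, never imputed. The fundamental is
refined by parabolic interpolation of log power, giving median errors well
below 0.1 Hz on simulated events (the acceptance check requires < 2 Hz
median over 200–800 Hz).

Events with any non-positive cross section are dropped with a logged reason;
no imputation.

## Classifier and evaluation

LDA is implemented directly (scikit-learn serves only as a cross-check
oracle in the test suite): features are z-scored on the training fold, the
pooled within-class scatter S_w gets a ridge of 10⁻⁶ · trace/dim for
invertibility on small folds, and the discriminant basis is the top C−1
unit-normalized generalized eigenvectors of (S_b, S_w). Prediction assigns
the nearest projected centroid (Euclidean in discriminant space, equal
priors), ties broken by label order; for two classes this reduces exactly to
the closed-form Fisher discriminant, which the tests verify on random
instances.

Evaluation: random under-sampling to the smallest class, stratified
leave-one-subset-out cross-validation (default k = 10; the number of folds
is a free choice — k = n recovers true leave-one-out), each fold tested
exactly once. This is repeated `n_repeats` times (default 1000; the demos
use 100), repeat r seeded with `seed + r` for both resampling and fold
assignment so any single number is reproducible in isolation. Metrics per
confusion matrix: overall accuracy (trace/total), per-class recall,
precision and F1; summaries are mean ± 1.96·SE over repeats. Undefined
per-class metrics (empty row/column) are excluded from that repeat's
average with a warning rather than coerced to zero. Because mean-of-F1 and
F1-of-means can differ, the report carries both (`f1_of_means`).

The reported CI quantifies resampling variability (under-sampling + folds)
on a fixed dataset; it does not cover dataset-level sampling variance, which
is why the stability check compares evaluation seeds on one feature set.

## Mass scaling

Under the Deakin power law f ∝ m^0.3, a WBF shift f₀ → f₁ implies a relative
mass change (f₁/f₀)^{1/0.3} − 1; for 347 → 365 Hz this is ≈ 18.4%. An
absolute change requires a baseline mass: `infer_baseline_mass` back-solves
it from a target change (0.91 mg ⇒ ≈ 4.96 mg baseline) and the resulting
estimate is flagged `baseline_inferred`, because that baseline is not a
measured quantity. The alternative mass estimate via depolarization/optical
path length is not implemented (no usable formula exists in the material
this package models).

## Problem sizes and numerical choices

Default demo/pipeline sizes: 100–300 events per class, 100 evaluation
repeats, k = 10; the parameter-recovery check uses 500 events per class. One
simulated event is ~5 000–8 000 samples (≈0.2 s of signal); the full
acceptance computation runs in seconds on one core. Seeds fan out from a
single global seed via `numpy.random.SeedSequence`; per-event seeds are
drawn below 2³¹. Degenerate inputs are explicit errors: transits shorter
than 32 samples, decomposition windows under 3 samples, zero-mean
calibration targets, classes smaller than the fold count, duplicate class
labels.

## Known limitations

* Synthetic-only validation: no measured events are available, so absolute
  classification accuracy on real mosquitoes is outside what the tests can
  establish; the defaults produce two-class accuracies in the mid-80% range,
  consistent with the motivating laboratory study, but that agreement is a
  plausibility check, not a reproduction.
* The body envelope estimator retains a small noise-dependent downward bias
  (≪1% at default SNR); at much lower SNR body-ratio features would need a
  bias-corrected envelope.
* Harmonic power ratios are read from interpolated Welch bins and inherit
  leakage at short event durations.
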