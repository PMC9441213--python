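# Methods

`specklesense` implements a complete, synthetic-data-backed version of a
magnetically assisted specklegram glucose-sensing analysis: simulate
multimode-fiber speckle videos whose temporal statistics encode a
glucose-dependent modulation at a magnetic drive frequency, track
speckle motion by sub-image cross-correlation, isolate the
drive-frequency component by FFT band selection, and classify glucose
levels with a triangle-kernel Naive Bayes model under grouped
cross-validation.  This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## 1. The physical picture being emulated

A multimode fiber carrying coherent light emits a far-field speckle
pattern — the interference of its guided modes.  Pressed against a
fingertip, with the cladding stripped over a short sensing region, the
evanescent tail of the guided field (penetration depth
d_p = λ / (2π √(n_eff² − n_s²)), about 141 nm for λ = 532 nm,
n_eff = 1.46, n_s = 1.33) interacts with the tissue; the transmitted
power follows P = P₀ exp(−γ_eff L/D).  An AC magnetic field applied to
the finger at a drive frequency f_d (140 Hz here) perturbs the
iron-bearing red blood cells; the resulting magneto-optic disturbance of
the leaked light modulates the speckle dynamics at f_d, more weakly at
higher glucose.  A *covered* fiber senses only glucose-independent skin
vibration at f_d.  The analysis chain therefore compares four sensing
cells (covered/uncovered × field off / field on, with or without
lock-in filtering) and should recover glucose only in the
uncovered-fiber, field-on, filtered cell.

## 2. The speckle simulator

**Modes.** Modes are random transverse plane waves: wavevectors uniform
in the Nyquist disc (|k| ≤ 0.5 cycles/px), phases uniform, amplitudes
uniform on [0.5, 1.5].  This is not a waveguide mode solver; plane-wave
superposition reproduces the one testable statistic the abstraction
needs — fully developed speckle (contrast → 1 as M grows; checked at
M = 100 within ±0.15).  All recordings of a dataset share a single mode
realization (a dataset-level mode seed): they model repeated
acquisitions on one instrument, where the fiber's speckle structure is a
fixed property of the setup and only the perturbations change between
recordings.  Per-recording mode sets are available by seeding
`simulate_recording` directly.

**Drive channels.** A magneto-optic or vibrational coupling at the
drive frequency must put a spectral line *at f_d* into the
correlation-peak-height trace.  A per-mode phase perturbation that is a
pure sinusoid at f_d cannot do that: the adjacent-frame peak height
depends on the phase increments only through |⟨e^{iΔφ}⟩|², which is
invariant under Δφ → −Δφ, so a sinusoidal Δφ yields only even harmonics
(2 f_d, DC).  The drive channels are therefore modeled as drive-locked,
amplitude-modulated phase jitter: per-mode white phase noise whose
standard deviation is d · (1 + sin 2π f_d t)/2.  The induced
frame-to-frame decorrelation — hence the height trace — then oscillates
at f_d directly, with amplitude growing monotonically with the
modulation depth d (verified end to end in the test suite).  The
glucose channel uses this form with d = modulation_depth, active only
when the fiber is uncovered *and* the field is on; the vibration channel
uses it with a fixed glucose-independent amplitude (0.05 rad) whenever
the field is on.

**Glucose → depth map.** Linear and strictly decreasing over the
reference range: d(g) = 0.3 − 0.25·(g − 86)/84 rad, i.e. 0.3 rad at
86 mg/dl down to 0.05 rad at 170 mg/dl, matching the observed monotone
decrease of speckle variation with glucose.  The quantitative mapping
from a 150 G field to a phase amplitude is not derivable from first
principles here; only the monotone trend is modeled.

**Interference.**  Three interferers share the same
envelope-modulated-jitter form, each with a random envelope phase per
recording (pulsatile tissue coupling is exactly the mechanism laser
speckle flowmetry exploits):

| channel      | amplitude (rad) | frequency (Hz) | role |
|--------------|-----------------|----------------|------|
| heartbeat    | 0.05            | 1.17           | physiological in-band-of-raw-trace interferer |
| respiration  | 0.03            | 0.25           | slow physiological interferer |
| rig hum      | 0.25            | 50             | mechanical hum of the drive rig (audio amplifier + solenoid); dominates the raw trace, fully rejected by the 140 Hz band |

plus a per-mode Gaussian random-walk drift (RMS 0.1 rad over 1 s) and
additive white intensity noise (σ = 0.5% of mean intensity).  These
amplitudes are the package's study conditions: they were chosen so the
interference dominates the *unfiltered* trace (the no-filter
configuration must sit well below the filtered one) while the
drive-band leakage they produce stays below the smallest glucose
amplitude gap the classifier must resolve.  The white-noise floor is
the binding constraint: its in-band residual after filtering scales the
within-class amplitude scatter, and the two tightest class pairs
(110/111 and 103/105 mg/dl, 1–2 mg/dl apart) have drive-amplitude gaps
of only ~1%.

**What the generator does not model.**  Tissue optics (scattering and
absorption coefficients), camera optics and defocus, inter-subject
variability, true Faraday rotation, and non-stationary physiology.
Passing tests on this generator show that the analysis chain recovers a
drive-locked, glucose-keyed modulation under realistic interference —
not that the method works on human data.

## 3. Tracking

Frames are tiled into sub-images (default 32×32, stride 32, search
radius 8 px for 128×128 frames; scaled-down grids for smaller frames).
The raw product-sum correlation R(dx,dy) = (1/NM) ΣΣ A(i,j) A′(i+dy,
j+dx) is retained as a public primitive (oracle-checked against a
literal double-loop evaluation to ≤1e−9 relative); peak *tracking* uses
the zero-mean unit-variance (Pearson) variant, which is bounded in
[−1, 1], invariant to affine intensity changes, and not biased toward
bright regions.  Conventions: 0-based (row, col); displacements
reported as (dx, dy) = (col, row) motion of the speckle from frame t to
its partner; A anchored centered in A′; valid-region sums with the NM
divisor for the raw form; integer-pixel peaks only (no subpixel
interpolation), ties broken by smallest |dx|+|dy|, then dy, then dx.
The batched implementation (FFT cross-correlation plus integral-image
window statistics) is tested for agreement with the single-pair path.
Per step the per-cell peaks are averaged over the grid; cells with
zero-variance templates are skipped, and a stack where every cell is
degenerate raises rather than returning silence.

## 4. Lock-in filtering

The drive component is isolated digitally: FFT (forward unnormalized,
inverse 1/n), zero every bin outside [f_d − h, f_d + h] together with
its conjugate mirror, always remove DC, inverse FFT.  The default pass
half-width is one FFT bin (the strictest reading of removing all other
components); the pipeline uses 1.0 Hz so that the drive line survives
the slight off-bin placement that arises because an adjacent-frame
trace has T−1 samples.  No window function is applied by default —
synthetic durations put the drive on or near an exact bin; a Hann
option (with its factor-2 coherent-gain compensation) exists for
real-world traces.  Analytic identities (two-tone separation, Parseval,
out-of-band residual ≤1e−9) pin the implementation down.

## 5. Features and classifier

The classified quantity is the band-filtered correlation-peak-height
trace, cut into fixed windows (50 samples, hop 36).  Two deliberate
choices here:

* **Windows are not individually rescaled.**  The glucose signature in
  the filtered trace is the *amplitude* of the drive tone; per-window
  max-abs normalization would erase it.  `segment_features` keeps raw
  amplitudes by default and offers row normalization as a flag.
* **The hop is not a multiple of the drive period** (7.14 samples at
  the defaults).  Successive windows then sample different drive
  phases, so each feature's class-conditional training density covers
  the tone's full swing (an amplitude-scaled arcsine-like law) instead
  of collapsing onto a single recording-specific phase.  A
  phase-invariant alternative (descending order statistics of the
  rectified window, `transform="sorted-abs"`) is provided; it
  concentrates each feature near a fixed quantile of the tone amplitude
  but was not found to help at the window level and is off by default.
* **The recording is the observation unit.**  Windows of one recording
  are repeated looks at the same physical measurement, so the pipeline
  majority-votes the out-of-fold window predictions within each
  recording (`aggregate="recording"`); bandwidth selection and the
  reported confusion matrix work on recording-level labels (70
  observations at the default study size).  Window-level reporting
  remains available.

The classifier is Naive Bayes with per-class, per-feature
triangle-kernel densities, f(x) = mean over training values v of
K((x−v)/h_j)/h_j with K(u) = (1−|u|)₊, evaluated in log space.  The
per-feature bandwidth is a single dimensionless h times the feature's
pooled training standard deviation (unit scale substituted for constant
features).  A test point outside every class's kernel support falls
back to the priors — a documented degenerate rule, not an error; ties
resolve to the lowest glucose class.  h is selected from a log-spaced
10-point grid (0.05–2) by mean cross-validated accuracy, ties to the
smaller h — a deterministic stand-in for Bayesian hyperparameter
search with the same selection criterion.

**Leakage control.**  Windows cut from one recording are highly
correlated, so folds are stratified by class *and* grouped by
recording (`StratifiedGroupKFold`): no recording straddles the
train/validation boundary.  This is the computational analogue of
re-positioning the finger between repeated recordings.  The 60/40
stratified holdout of the original protocol is implemented alongside.

## 6. Pipeline and problem sizes

`run_configuration` chains simulate → track → (band-filter |
normalize) → segment → cross-validate deterministically from one master
seed; `run_all` repeats this over the sensing configurations with a
shared seed family and renders a comparative table (accuracies in
percent, one decimal).  Only the qualitative structure of the
comparison is claimed: lock-in filtered ≫ unfiltered > covered-fiber
chance.  The human-data accuracies of the original study are neither
targets nor reproducible from synthetic data, and the generator is not
tuned toward them.

Default problem sizes are the package's own choice for desk-scale
reproducibility: 64×64-pixel frames, 1.5 s at 1 kHz, 96 modes, 14
glucose levels × 5 recordings (70 recordings per configuration), a 2×2
tracking grid of 24×24 sub-images with search radius 6, and a pass
half-width of 2/3 Hz (one to two bins of the 1499-sample trace).  A
"quick" scale (48×48, 0.35 s, 24 modes, single tracking cell) supports
multi-seed ordering checks.  The original recordings are 128×128;
nothing in the chain depends on the frame size beyond statistics.

## 7. Numerical choices and degenerate inputs

* Rendering uses complex64 matrix products (relative error ~1e−7, far
  below every speckle statistic of interest); all analysis stages run
  in float64.
* FFT-based correlation is validated against exact sums at ≤1e−9
  relative; normalized-correlation denominators are clipped at zero
  and zero-variance windows score 0.
* All-zero traces normalize to themselves; empty classes, singleton
  classes in holdout, classes smaller than k in CV, Nyquist-violating
  drive settings, and non-finite inputs raise typed validation errors.
* Seeds: a master seed expands through `numpy.random.SeedSequence`
  keyed by (seed, counter) into independent child streams per recording
  and per noise channel, so any recording is reproducible in isolation
  and disabling one channel does not shift the others.

## 8. Known limitations

* The magneto-optic coupling is phenomenological; the modulation-depth
  scale is a free parameter, not derived from field strength.
* Integer-pixel tracking quantizes displacement; the analysis relies on
  peak height, which is unaffected.
* Kernel Naive Bayes treats window samples as conditionally
  independent; they are not (one window is one tone phase), which is
  harmless for classification but makes the posterior probabilities
  overconfident.
* The two tightest reference classes (110 vs 111 mg/dl) differ by ~1%
  in drive amplitude and remain partially confusable at the default
  noise level — visible as the dominant off-diagonal block of the
  confusion matrix, mirroring the structure such an instrument would
  show in practice.
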