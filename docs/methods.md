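# Methods

## Signal model and scope

The pipeline targets single-channel surface EMG of the vastus medialis at
1 kHz with a synchronized knee goniometer and auditory pacing tones. Four
motion classes are distinguished: standing leg lift, seated leg extension,
and the stance and swing phases of walking. Physiological surface EMG
carries essentially all of its power between roughly 10 and 500 Hz; the
feature models below are designed around that band.

## Preprocessing

* **High-pass filter.** Butterworth, 20 Hz cutoff, order 4, applied
  forward–backward (`zero_phase=True`, the default). Zero-phase application
  is chosen so filtering does not shift burst onsets relative to the angle
  trace; the squared magnitude response doubles the nominal attenuation
  (≥ 40 dB at 5 Hz for the default design). Cutoff and order are
  configurable; the cutoff must be below Nyquist.
* **Segmentation** follows the goniometer. A trial is a contiguous angle
  excursion above `angle_threshold_deg` (default 10°), with boundaries
  refined outward to where the angle returns below `boundary_floor_deg`
  (default 1°). Accepted durations default to 500–5000 ms. In a
  standing-sitting session each trial must follow a pacing tone within
  `tone_horizon_ms` (4 s).
* **Labelling** is kinematic. Standing-sitting: a trial whose peak flexion
  reaches `standing_peak_threshold_deg` (55°) is standing (the leg lift
  flexes the knee deeply), otherwise sitting (the seated extension is a
  shallower excursion). Walking: an excursion peaking at
  `swing_peak_threshold_deg` (40°) or more is the swing-phase flexion peak;
  shallower bumps are the load-bearing stance phase. A tone-order log would
  be an alternative labelling key for standing-sitting sessions, but the
  protocol randomizes motion order and no such log is part of the recording
  format, so the kinematic rule is used.
* **Onset detection** (`detect_onset_zc`) supports tone-paced protocols: the
  gated zero-crossing rate in a sliding 100 ms window must exceed 3× its
  mean over the 500 ms before the tone (and an absolute floor of 5
  crossings/window so silence cannot self-trigger), within 2 s of the tone.
  The window, factor, baseline and horizon are parameters; the defaults are
  package choices, as no standard constants exist for this mechanism.

## Features

Time-domain (MAV, RMS, iEMG, ZC) and frequency-domain (MNF, MDF) formulas
are as in the README. Notes:

* The ZC sign gate is strict: a sample exactly at zero never counts as a
  crossing. The default amplitude-difference threshold is 0 µV.
* No amplitude normalization is applied to iEMG by default; values are
  carried in the recording's own (µV-scale) units throughout.
* The Welch PSD uses a Hamming window, 256-sample sub-windows, 50% overlap,
  one-sided density scaling. MNF and MDF are invariant to the PSD's scale,
  so only the parameters that change spectral *shape* (window length,
  overlap) matter; 256 samples at 1 kHz gives ≈ 3.9 Hz resolution, adequate
  for summary frequencies of a 10–500 Hz process. MDF is resolved
  discretely — the first bin whose cumulative power exceeds half the
  total — not interpolated.

### Wavelet-SVD features

Five-level `db4` decomposition with **periodized** extension, which makes
the transform orthogonal. Segments are zero-padded to the next multiple of
2^5 = 32 before decomposition: periodization is only orthogonal when every
level halves to an integer length, and zero padding achieves that without
changing the signal's energy, so `Σ coeff² = Σ x²` holds exactly (to
~1e-15 relative) at any segment length ≥ 64. Sixty-four samples is the
hard minimum — the shortest dyadic length with a non-empty level-5
approximation.

Band annotations are derived from the sampling rate: cDl covers
(fs/2^(l+1), fs/2^l) and cA5 covers (0, fs/64); at 1 kHz that is 250–500 Hz
for cD1 down to 0–15.625 Hz for cA5. (Published tables for this feature
model sometimes print 256–512 Hz etc., which presumes a 1024 Hz rate; the
fs-derived edges are used here.)

Stacking the six coefficient sequences as rows of one matrix is not
well-defined — their lengths differ by design — so two concrete
compressions are provided:

* **per-band** (default): each sequence is a 1×L matrix whose single
  nonzero singular value is its Euclidean norm; exactly one parameter per
  band is retained, the features stay aligned to named bands, and their
  squares partition signal energy.
* **stacked**: zero-pad to a common length, stack into a 6×L matrix, take
  its six singular values (non-increasing, permutation-invariant across
  rows). Provided for sensitivity analysis; band identity is lost.

## Classifier and evaluation protocol

* Kernel SVM with one-vs-one voting (the canonical multiclass extension of
  the binary discriminant). Default kernel RBF; polynomial and linear are
  available.
* Features are standardized with training-fold means/SDs only — no test
  leakage.
* RBF width: median heuristic, γ = 1/(2·m²) with m the median pairwise
  distance among standardized training rows (fallback 1/d if degenerate).
* Regularization C: inner stratified 5-fold CV over the grid 2⁻³…2⁹ by
  powers of two; ties break to the smallest C (the least complex model).
* Repeated CV: per repeat, a fresh stratified shuffle into 5 folds; each
  fold is once the 20% test set. Stratification keeps ≈ 20% of every class
  in each fold, which matters with 40-member classes. The reported SD is
  over all repeats × folds fold accuracies. Per-repeat seeds derive from
  one root seed via `numpy.random.SeedSequence`, so the whole protocol is
  bit-reproducible, and feature-set comparisons at one seed share identical
  partitions (paired design).
* Statistics: one-way ANOVA across motion classes for a single feature, and
  two-sided paired t-tests, via `scipy.stats`; groups with zero variance
  everywhere, or fewer than two groups of two, are rejected as degenerate.

## Synthetic-data generator

The generator emulates interference-pattern EMG as **amplitude-modulated
band-limited Gaussian noise**: white noise shaped by an order-4 Butterworth
band-pass (unit RMS), multiplied by a class-specific envelope and amplitude,
plus a white noise floor. Default class signatures:

| class    | band (Hz) | envelope     | amplitude | duration | peak angle |
|----------|-----------|--------------|-----------|----------|------------|
| standing | 30–120    | trapezoid    | 12 µV     | 2000 ms  | 70° |
| sitting  | 60–200    | trapezoid    | 14 µV     | 2000 ms  | 40° |
| stance   | 100–320   | double-burst | 22 µV     | 840 ms   | 18° |
| swing    | 160–450   | low-flat     | 18 µV     | 560 ms   | 60° |

plus an 8 µV noise floor, lognormal per-trial gain jitter (σ = 0.4) and
per-subject gain (σ = 0.15) over 14 subject labels. The bands overlap
deliberately: with disjoint bands every feature set saturates at ~100%
accuracy and the feature-set comparison degenerates; the overlapping regime
keeps the task non-trivial (time ≈ 90%, frequency ≈ 96%, wavelet-SVD ≈ 99%
at the defaults) while preserving the qualitative structure — gait phases
stronger, faster and higher-band than the slow volitional motions, the
swing envelope flatter than the stance double burst. Default dataset counts
are 40 standing, 40 sitting, 90 stance, 90 swing (260 trials).

Session recordings alternate tone-paced trials (1 s pacing, 5 s rest) for
standing-sitting, or chain 1400 ms gait cycles (60% stance / 40% swing) for
walking, with trapezoidal knee-angle profiles (brisk 15% ramps) so phase
boundaries are kinematically sharp. Everything is deterministic under the
seed at every granularity.

**What the generator does not emulate:** motor-unit action-potential
structure, fatigue-related spectral compression, ECG/motion artifacts,
electrode-lift dropouts, realistic inter-subject spectral variability, or
smooth goniometer dynamics (real knee-angle curves have no flat plateaus and
noisier rest baselines, so real segmentation accuracy will be lower than the
near-perfect recovery measured here). Passing the synthetic benchmark
demonstrates that the pipeline's mathematics and protocol are correct and
that band-resolved energy features separate band-separated classes; it does
not certify recognition accuracy on recorded EMG.

## Numerical choices and problem sizes

* Energy-conservation and formula-equivalence checks use tolerances of
  1e-10 relative (exact integer equality for ZC).
* SVD values are validated against the √eigenvalue route of the Gram matrix
  at 1e-8 absolute.
* Degenerate inputs: empty segments, all-zero spectra, single-class
  training sets, sub-64-sample segments and non-positive C grids raise typed
  errors rather than returning sentinel values.
* The test suite evaluates the end-to-end comparison at 10 CV repeats and
  the ANOVA type-I simulation at 400 replicates; the acceptance script runs
  the full 50-repeat protocol. These sizes are the package's own defaults
  for a quick, deterministic check; all are parameters.

## Known limitations

* The per-band SVD compression discards within-band temporal structure;
  two signals with equal band energies are indistinguishable to the wtsvd
  features regardless of envelope shape.
* The pooled (subject-mixed) CV protocol estimates accuracy for subjects
  represented in training; it is not a leave-one-subject-out generalization
  estimate.
* The kinematic standing/sitting labelling rule assumes the two motions
  have distinguishable flexion depths; protocols where they do not would
  need a tone-order log instead.
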