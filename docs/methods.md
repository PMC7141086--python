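# Methods

This note documents the models, parameters and numerical choices behind
`pupilcascade`, and what the synthetic validation does and does not show.

## Signal model

A trial is a pupil-size series y(t) sampled on a uniform grid (25 Hz by
default), modelled as the superposition of

- a **slow non-stationary trend** over minutes (fatigue, accommodation,
  gradual luminance change),
- **spontaneous band-limited fluctuation** in the slow hippus range,
- **broadband measurement noise** from the pupil detector,
- **artifacts**: blinks/tracking losses (reported as size 0), eyelid-
  occlusion bias just before and after blinks, single-sample glitches, and
  gross detector failures (e.g. locking onto the iris),
- sparse **evoked dilation transients** at hazard onsets.

All detection thresholds are expressed in per-trial standard deviations,
so the pipeline is agnostic to whether "size" is a diameter or an area and
to the device's units.

## Preprocessing

Applied in strict precedence (each rule sees only samples surviving the
previous ones): input-invalid samples (blinks/losses); a ±2-sample (40 ms)
margin around each blink run, because a half-closed eyelid biases the
reported size low; samples differing by more than 10% (relative) from the
last still-valid value; samples more than 3 SD from the trial mean, with
mean/SD computed in a single pass over the samples surviving the earlier
rules (symmetric deviation — detector failures can err in either
direction).

The 10%-jump reference is the last still-valid sample, so one glitch
cannot re-anchor the reference. A frozen reference, however, can cascade
without bound when a glitch happens to precede a genuine slow excursion:
every subsequent sample then differs from the stale reference and the
whole excursion is invalidated. Because detector glitches span at most a
handful of samples, the rule re-anchors after `max_jump_run = 5`
consecutive flags: anything longer is a genuine level change, not an
artifact.

Gaps are filled by linear interpolation between the neighbouring valid
samples; leading/trailing gaps take the nearest valid value. Interpolated
samples still count as invalid for the quality gate: a trial needs
≥ 75% genuinely valid samples (boundary inclusive). The first 30 s of
every trial are discarded as an acclimation phase before any of this.

## Wavelet machinery

Multiresolution analysis uses Daubechies-4 (db4) wavelets throughout
(PyWavelets backend; a single wavelet family keeps the codebase and its
boundary handling uniform). `D_1` denotes the finest detail band. The
default boundary mode is symmetric half-point padding; exact Parseval
checks use periodized transforms on dyadic lengths, where orthogonality is
exact to rounding.

**Detrending.** The trend is the reconstruction of the approximation band
at level 9: at 25 Hz, A₉ covers frequencies below ≈ 25/2¹⁰ ≈ 0.024 Hz,
i.e. periods above ~40 s — the drift-over-minutes band — while leaving the
1–2 s scale of evoked responses untouched. The level is configurable; 9 is
the deepest level that still removes multi-minute drift without touching
hippus-band fluctuation.

**Relative band energy.** For a decomposition with detail energies
e_j = ΣD_j² and approximation energy e_A, the relative energy of band j is
e_j / (Σ_k e_k + e_A); the shares sum to one whenever total energy is
positive, and are defined as zero for an all-zero window.

## Candidate peaks

Extrema are stationary points of the Gaussian-smoothed signal (smoothing
the central-difference derivative is identical to differentiating the
smoothed signal), located as negative-going zero crossings of the smoothed
derivative. The smoothing SD is 2 samples (80 ms at 25 Hz). The amplitude
gate reads the smoothed value at the extremum — the quantity the extremum
actually belongs to; reading the raw sample there would gate on
single-sample noise — and keeps candidates exceeding 1.5 × SD of the full
detrended trial. Only maxima are kept: the cascade classifies dilations.

Two dilation peaks closer than one response span cannot be distinct
physiological events, so candidates within 2.5 s of a higher candidate are
suppressed. Suppression uses local dominance (a candidate survives iff no
higher candidate lies within the radius; ties break toward the earlier
peak) rather than greedy highest-first pruning: the decision then depends
only on a fixed neighbourhood, which keeps detection exactly
translation-equivariant away from trace boundaries.

Each surviving candidate gets a least-squares quadratic fit
y = a + b·u + c·u² (u = t − t_peak) over ±1.25 s; fits with c ≥ 0 (not a
maximum) or fewer than 5 in-trace samples are discarded. The FWHM derives
from the fitted curve with the window minimum of the parabola as baseline:
with peak height h above that baseline, FWHM = 2·√(h / (2|c|)).

## Features and labelling

Per candidate, the 75-sample window (37 samples each side of the peak at
25 Hz) is decomposed to level 4. The A₄ reconstruction within the window
gives amplitude (max − window minimum), mean, and area (trapezoidal
integral above the window minimum, dt = 40 ms); D₁–D₄ give four relative
energies. Features are computed on the detrended signal, where detection
operates. Windows that would extend beyond the trace drop the candidate
(logged) rather than zero-padding silently.

Ground-truth labelling matches each annotated hazard to the earliest
candidate whose peak time lies within [onset, onset + 2.5 s] (one response
span); each event claims at most one candidate, all unclaimed candidates
are noise, and unmatched events are recorded as missed detections.

## Classification and evaluation

An RBF-kernel SVM (C = 1, gamma = 1/(n_features · var), features z-scored
with training-fold statistics) is trained on class-balanced data: minority
rows are duplicated uniformly at random until parity — duplication rather
than synthetic interpolation, so the set of distinct minority points never
changes. Cross-validation is leave-one-subject-out: oversampling and
standardization happen inside each training fold only. Rows are
canonicalized (by subject, then peak time) before folding, so results are
invariant to input ordering. A fold whose training set lacks a class is
skipped with a warning.

Hyperparameter grids (C up to 100, several kernel widths) and
sensitivity-favouring operating thresholds derived from training-fold
score quantiles were evaluated during development and rejected: the
defaults sit at the feature-level ceiling (a boosted-tree reference
classifier does no better), the derived threshold collapses to ~0 because
training hazards are fully separated after oversampling, and both
alternatives only traded precision for no sensitivity gain.

Sensitivity is event-level — hazards that never produced a candidate count
as false negatives — while specificity and precision are candidate-level,
where true negatives exist. Zero-denominator rates are reported as
undefined, never as 0. The ROC sweeps the decision threshold over all
observed held-out scores; AUC is the trapezoid over that curve (equal to
the Mann–Whitney rank statistic, which the tests verify). Per subject the
report also carries D (candidates entering classification) and F (false
positives surviving it).

## Synthetic generator

The generator is the package's test bed and defines known ground truth.
Defaults emulate the target recording conditions: 2400 s drives at 25 Hz,
baseline 4.0 arbitrary units, nine hazards per drive at least 10 s apart
and at least 40 s from trace start (so they survive the trim), ~12
blinks/minute of 2–5 samples written as zero-runs, 2 gross outliers/minute
at 4–6 trial SD from the mean, drift as a random sum of sinusoids with
periods 120–600 s and total amplitude 0.3 × baseline, white noise with
SD 0.02 × baseline, and band-limited fluctuation in the 0.03–0.15 Hz slow
hippus range.

The fluctuation amplitude (SD 0.003 × baseline) encodes two facts about
the emulated setting: the simulated environment's brightness varies only
about ±5%, so luminance-driven fluctuation is weak; and the cascade's
absolute 1.5-SD gate presumes that an evoked dilation of ~2 SD is
detectable regardless of where on the background it lands, which bounds
the slow background's share of total variance (the white-noise wander that
survives 80-ms smoothing already contributes ~0.26 of the detrended SD,
leaving ≤ ~0.15 for the slow share). With these defaults a drive yields
roughly 20–35 candidate peaks, of the same order as the tens of candidate
peaks per drive the method reports on real recordings.

The evoked kernel is zero during the reaction latency (0.2–0.35 s), rises
as a smoothstep to its peak 0.5–1.0 s after onset, and returns to baseline
by 2.0–2.5 s through a raised-cosine envelope carrying two geometrically
decaying return waves (the oscillatory return). The apex is C¹ — rise and
decay both have zero slope there — because real dilation velocity passes
smoothly through zero; a corner would be artificially blunted by the
detection smoothing. Latency and time-to-peak are correlated (rise time
≥ 0.3 s): a late-reacting pupil cannot complete its rise instantly. Peak
amplitude is parameterized in units of the trace's non-event SD
(default 2.5), so the 1.5-SD candidate gate is exercised at a known,
seed-independent contrast.

**What the generator does not emulate:** luminance-locked PLR responses to
scene changes, saccade- and gaze-angle-dependent pupil foreshortening,
slow asymmetric drifts (sinusoidal drift is stationary in distribution),
heavy-tailed detector noise, or spurious peaks with event-like shape from
other arousal sources. Passing end-to-end tests therefore shows that the
cascade recovers transients of the stated shape and contrast from
realistic artifact levels — not that the classifier's operating point
would transfer unchanged to real drives, where spurious peaks can be more
event-like and evoked amplitudes vary between subjects.

## Problem sizes and determinism

The shipped validation runs five independent 8-subject cohorts (40
full-length drives, ~2.4 M samples) through the complete cascade — about a
minute on one CPU. Every random quantity derives from a single seed;
per-subject seeds are `global_seed + crc32(subject_name) mod 2³¹`, so
growing a cohort never changes existing subjects' traces. Under these
frozen conditions the cascade measures pooled held-out event-level
sensitivity ≈ 0.85, candidate-level precision ≈ 0.81–0.84, mean ROC AUC
≈ 0.95, and ~99% of matched detections within 0.5 s of the true evoked
peak (`scripts/acceptance.py` recomputes all of these).

## Known limitations

- The 75-sample feature window is short for a level-4 db4 decomposition:
  every coefficient feels the window boundary. This is inherent to the
  window/level pair; the A₄ features remain faithful for bumps whose
  energy lies in the approximation band (verified to 15% in tests).
- The level-4 approximation band at 25 Hz ends near 0.78 Hz, so the A₄
  amplitude of a fast-rising transient (rise ≲ 0.4 s) underestimates its
  true height by up to ~25%; the classifier sees consistent features, but
  the amplitude feature is not a calibrated physical height.
- Event matching is greedy-earliest within a fixed 2.5-s window; two
  hazards closer than one response span cannot both be matched (the
  generator enforces 10-s spacing, real annotations should too).
- QC, detection and labelling are per-trial and unit-free, but the SVM
  features `mean` and `amplitude` are in signal units; cross-device
  transfer relies on the per-fold standardization.
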