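# Methods

`pdwear` is a tested re-implementation of a wearable-sensor analysis of
Parkinson's-disease motor symptoms: random-forest classifiers for tremor and
bradykinesia trained on engineered inertial features, evaluated under
leave-one-participant-out (LOPO) cross-validation, and stress-tested along
three measurement axes — which sensors are worn, how fast they sample, and
which feature categories are computed.  Because the clinical dataset such an
analysis would normally use is restricted, the package includes a synthetic
cohort generator whose output has the statistical structure the analysis
assumes; every downstream stage is exercised against that generator.

## The synthetic cohort

The generator emulates a two-visit clinic protocol.  Each of 13 synthetic
participants repeats a battery of 13 standardized motor tasks (gait, fine and
gross upper-extremity, clinical assessment, postural holds) 7 times: once in
the OFF-medication state, five times at 30-minute intervals after a dose, and
once more at a later ON-state visit.  A simulated clinician scores tremor and
bradykinesia per task repetition on the 0–4 MDS-UPDRS-style scale.
Recordings come from two devices on the same arm: a hand sensor (tri-axial
accelerometer ±4 G and gyroscope ±1000 deg/s at 62.5 Hz) and a wrist watch
(tri-axial accelerometer at 50 Hz), with recording lengths drawn from 15–60 s.

### Scoring model

Each participant carries latent severities (`tremor_propensity`,
`brady_propensity`, both in [0, 4)) and the observed score for repetition
*k* is

    score = clamp(round(propensity · medication_response(k) + ε), 0, 4)

with clinician noise ε ~ N(0, 0.35²) truncated at ±2σ.  The medication
response falls from 1.0 (OFF) to 0.25 over repetitions 1–6 and is 0.35 at the
second visit; this deep OFF→ON sweep is what gives most participants clips on
both sides of the symptom-presence threshold, which the paired LOPO analyses
require.  Propensities are drawn from a two-component mixture (a symptom-free
majority near 0 and an affected minority capped at 2.75 for tremor, 2.4 for
bradykinesia).  With these caps and the noise truncation a score of 4 can
never occur, and roughly two thirds to three quarters of tremor-scored clips
are score 0 — matching the heavy class imbalance such cohorts show.
Bradykinesia is not scored on the three postural-hold tasks (too little
voluntary movement), so bradykinesia models see about three quarters as many
clips as tremor models.  The noise term is a free parameter of the generator,
not an estimate of real inter-rater variability.

### Kinematic model

Ideal hand motion is synthesized on a dense 200 Hz grid as a sum of:

* **gravity** — a 1 G projection with slowly varying orientation
  (~0.02–0.06 Hz wander), the component the 0.5 Hz high-pass later removes;
* **voluntary movement** — a task-archetype oscillation at the task's base
  frequency (0–3 Hz, within the 0–5 Hz range typical of human movement),
  multiplied per recording by a tempo factor U(0.8, 1.25) because people
  naturally move at different speeds.  Bradykinesia at score *s* scales the
  frequency and the angular-velocity amplitude by a monotone slowing factor
  (1.0 down to 0.4 at score 4) and adds a within-recording amplitude
  decrement proportional to the score.  The linear-acceleration amplitude is
  scaled only weakly (exponent 0.35 on the slowing factor by default;
  exponent 0 in the "gyro-encoded" study regime), reflecting that angular
  velocity is the cleaner carrier of slowness at the wrist;
* **tremor** — a sinusoid with frequency drawn from the characteristic
  4–6 Hz band, acceleration amplitude set by the tremor score (0, 0.5, 1.2,
  2.5, 4.0 m/s² for scores 0–4), slow amplitude modulation at 0.25 Hz, and a
  random spatial orientation.  The gyroscope sees the same oscillation at
  15 deg/s per m/s², consistent with a hand oscillating about the wrist;
* **white process noise** on both channel groups.

The sensor model samples this motion with Gaussian timestamp jitter (2 ms SD,
clipped below 40% of a sample period so time stays strictly increasing),
drops each sample independently (2% by default), adds measurement noise
(0.01 G accelerometer, 1 deg/s gyroscope), and clips to the device ranges.
The watch sees the same motion attenuated by 0.9 with its own independent
noise and no gyroscope — the two accelerometers therefore carry nearly the
same information, as wrist and hand placements do in practice.

### What the generator does not model

Realistic biomechanics (limb dynamics, multi-joint coupling), medication
pharmacokinetics, freezing of gait, rigidity, dystonia, bilateral asymmetry,
and task-specific movement texture are all absent.  Signals are generated
*from* the recorded score, so label noise never decouples the label from the
signal the way a disagreeing human rater would.  Passing tests therefore
demonstrate that the pipeline recovers the structure this model plants —
band-limited tremor power, angular-velocity slowing — not that the same
AUROC levels would be reached on real patients.

## Preprocessing

The conditioning chain is fixed: cubic-spline interpolation onto the device's
nominal uniform grid (≥4 samples required, no extrapolation beyond the
recorded span), rational polyphase downsampling (`scipy.signal.resample_poly`;
62.5→7.5 Hz is up 3 / down 25, with the anti-alias low-pass built into the
filter bank), a zero-phase 4th-order Butterworth high-pass at 0.5 Hz on the
accelerometer channels only (removes the orientation/gravity component;
gyroscope passes through untouched), then segmentation into 5-s windows with
50% overlap.  Filtering is applied per recording, before segmentation, to
avoid 5-s-window edge transients.  Window length is `floor(5 · rate)` samples
(312 at 62.5 Hz, a ≤0.5% truncation of the non-integer 312.5) with a hop of
half a window.  A clip is valid only if the *un-interpolated* recording had
at least 80% of the expected samples (5 s × the device's native rate) inside
the window; invalid clips are excluded from all modeling.  For a drop-free
60 s recording at 62.5 Hz this yields exactly 23 valid clips.

Note the high-pass has unit gain only well above its cutoff: a ~0.6 Hz
component survives, and a single 5-s window of it integrates to a residual
mean of order 0.1 × SD.  DC removal is exact at the recording level (a
constant input leaves <1e-6 of its magnitude away from the edges), but
per-clip means are only approximately zero.

## Features

74 features per sensor modality per clip, in five categories, computed on
the three axes and on the per-sample Euclidean magnitude (57 tri-axial + 17
magnitude); both modalities give 148.

| category | per source | definition |
|---|---|---|
| T time | rms, range, mean, variance, skew, kurtosis | population moments, excess kurtosis |
| F frequency | dominant frequency, relative magnitude, PSD mean/sd/skew/kurtosis | Hann periodogram of the mean-removed clip, 0 Hz bin excluded |
| E entropy | SampEn(m=2, r=0.2·SD) | Chebyshev template matching, self-matches excluded |
| C correlation | peak and signed lag per axis pair (XY, XZ, YZ) | normalized cross-correlation; tri-axial only |
| D derivative | mean, sd, skew, kurtosis of the first difference × rate | forward differences |

Conventions adopted where the definitions were genuinely open:

* *Relative magnitude* is the dominant bin's power divided by total power, a
  normalized dominance measure.  Under the Hann taper an exactly on-bin tone
  puts at most 2/3 of its power in the dominant bin (window power weights
  1/4, 1/16, 1/16 across three bins).
* *PSD moments* are spectral moments — moments of frequency treating the
  normalized PSD as a probability mass over bins — so the PSD mean is the
  spectral centroid (≈ rate/4 for white noise).  The alternative reading
  (moments of the PSD ordinates) is scale-dependent and was rejected.
* SampEn uses the de-facto standard m = 2, r = 0.2 × clip SD, the same
  `n − m` template offsets for both lengths, and each unordered pair counted
  once.  A constant clip returns 0; if no template pair matches at either
  length the documented cap `ln(nt·(nt−1))` is returned.
* Cross-correlation ties break toward the smallest |lag| (then the negative
  lag); a zero-variance axis yields peak 0, lag 0.
* Degenerate signals (zero or rounding-level variance) take skew 0,
  kurtosis 0.
* Gyroscope channels are never high-pass filtered (angular velocity has no
  gravity offset); their features come from the regularized/downsampled
  signal directly.

The magnitude-only variant keeps the 17 magnitude features per modality plus
the 6 tri-axial correlation features (which have no magnitude counterpart),
i.e. 23 per modality.

Per-category computation cost is measured as median wall time over repeated
extraction of a fixed clip batch; preliminaries shared between categories
are charged once per combination, so timings are subadditive.  Timing is
hardware-dependent: reports carry both the milliseconds and the rank order,
and all statistical claims use AUROC only.

## Models and evaluation

Random forests with 50 trees (other hyperparameters at scikit-learn
defaults, seed fixed), one model per symptom × mode.  Binary models predict
symptom presence (score ≥ 1 vs 0); multiclass models predict the 0–4 score.
Evaluation is strictly LOPO: all clips of one participant — including
overlapping windows — are held out per fold, so window overlap can never
leak across the train/test boundary; all preprocessing is per-recording, so
no cross-participant statistics exist anywhere in the pipeline.

AUROC is pairwise concordance with ties counted ½ (equivalent to the
trapezoidal ROC area), computed via midranks.  Multiclass AUROC is the
prevalence-weighted mean of one-vs-rest AUROCs over the classes present in
the held-out participant's data; absent classes are skipped and the weights
renormalized (the weighting scheme is a documented choice).  A binary fold
whose test set contains a single class is unevaluable: it is excluded with a
logged warning, and paired analyses use only folds evaluable under every
condition.

## Sensitivity analyses

Each analysis forms a complete folds × conditions AUROC matrix (a paired
design: identical clips per fold across the hand-sensor conditions; the
watch pairs at the participant level) and applies a one-way repeated-measures
ANOVA with folds as subjects, F = MS_condition / MS_(fold × condition), df
(k−1, (n−1)(k−1)), no sphericity correction.  If significant at α = 0.05,
paired post-hoc t-tests follow with Holm–Bonferroni family-wise correction:

* **sensor sets** — Combo (148 features), Accel, Gyro (74 each, hand
  sensor), Watch (74); one-tailed tests of the Combo benefit over each other
  condition, two-tailed for Accel vs Watch (hardware/placement);
* **sampling rates** — 62.5, 50, 40, 30, 20, 10, 7.5, 5 Hz (watch from 50),
  each rate re-entering the pipeline at the downsampling stage; one-tailed
  tests of the original rate against each lower rate.  The carried-forward
  sensor set is Accel for tremor and Combo for bradykinesia;
* **feature sets** — all 31 non-empty category combinations at 30 Hz, timed
  and scored; combinations not on the cost/performance Pareto frontier
  (AUROC not above every cheaper combination, compared at full floating
  precision) are discarded before the ANOVA; one-tailed tests compare the
  costliest retained set against each other retained set.  A magnitude-only
  variant repeats the analysis with the reduced feature set.

Degenerate statistics are handled explicitly: identical condition columns
give F = 0, p = 1 (sums of squares at rounding level are snapped to zero);
zero-variance paired differences return t = 0, p = 0.5/1.0 when all-zero and
±∞ with the corresponding tail probability when constant nonzero.

## Study scale and replicate policy

The sensitivity analyses in the test suite and acceptance script run on a
reduced cohort chosen once: 8 participants, 6 tasks (all voluntary
frequencies ≤ 2 Hz, one non-scorable hold), 4 repetitions covering the
OFF→ON sweep, recordings 15–20 s.  The findings probed are orderings —
tremor classification collapses when sampling falls below its 4–6 Hz band
(5 Hz sampling Nyquist-limits content to 2.5 Hz), bradykinesia does not;
angular velocity carries the slowing signature; the entropy category is the
costliest to compute — and are scale-free, unlike absolute AUROC levels,
which run higher on the cleaner synthetic cohort than on real patients.
Stochastic checks run over 10 dataset seeds and are judged by majority
(8 of 10 for the bradykinesia rate-insensitivity check); a seed on which the
paired design cannot complete counts as a failure.  The sensor-set check
uses the gyro-encoded regime (accelerometer slowing exponent 0); the model
sanity check uses a strong-effect regime (tremor amplitudes doubled) against
a shuffled-label permutation null.

## Known limitations

* The cohort generator is a statistical stand-in, not a biomechanical model;
  effect sizes are controllable inputs, so only directions and orderings of
  effects transfer to real data.
* Scores and signals are generated jointly, so clinician disagreement—label
  noise uncorrelated with the signal—is not represented.
* Computation-time measurements depend on the host; only their ranks are
  asserted.
* Multiclass AUROC weighting and the handling of folds with missing classes
  are documented choices among several defensible ones.
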