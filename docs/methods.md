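# Methods

This note documents the measurement model, the statistics, the synthetic
data generator, and the numerical choices behind `assessgame`.

## The assessment being modelled

A child sits on a standardized seat wearing six pairs of 3-axis
accelerometers, one pair (proximal = reference, distal) over each hip, knee
and ankle. One joint per trial is the *target joint*: after calibrating the
game to the joint's maximum active range of motion (ROM), the child steers
an avatar vertically along a star-studded target path using only that
joint's flexion/extension, keeping inside 90% of the active ROM. A trial is
a 25 s accommodation phase followed by a 30 s test phase; only the test
phase is scored. Joints with an active ROM below 10° cannot be tested and
are excluded (with their comparator ratings) from all paired analyses.

Two scores are computed per trial, both standardized against a reference
cohort of neurologically intact adults (n = 31 in the emulated design) and
both "larger = worse":

* **Accuracy score** — the RMS error between the avatar trace and the
  target path over the test phase, in normalized screen units, divided by
  the adult SD of that error for the same target-joint context:
  `AS = RMSE / σ_adult`. The accuracy score is deliberately *not* centered
  (the wording of the source method standardizes *to* the adult SD); a
  `centered_accuracy` switch exposes `(RMSE − μ_adult)/σ_adult` for users
  who prefer a zero-mean adult baseline.
* **Involuntary movement score (IMS)** — for each of the five nontarget
  joints, the mean absolute angular speed over the test phase is expressed
  as a z-score against the adult reference for that (target joint,
  nontarget joint) context; the IMS is the mean of the five z-scores:
  `IMS = mean_j (m_j − μ_j) / σ_j`. It is not clipped, so a child who
  fidgets less than the average adult can score slightly below 0.

Per participant and occasion, the six per-joint scores are summarized as
the mean over the more-affected leg, the less-affected leg (labels come
from the clinical diagnosis, never from the scores) and all available
joints (total).

### Sensor-to-angle model

Each sensor's sagittal inclination is `atan2(a_x, −a_z)` of its gravity
components after a zero-phase 4th-order Butterworth low-pass at 3 Hz; the
joint angle is distal minus proximal inclination, so whole-segment
(compensatory) motion cancels exactly. The quasi-static assumption (the
accelerometer reads mostly gravity) is reasonable for slow seated
single-joint movements; linear-acceleration artifacts are treated as noise
and attenuated by the low-pass. Sustained sub-0.3 g readings are flagged as
unreliable. Angular speed is the forward difference times the sampling rate
with the last value repeated, keeping speeds and angles the same length.

### Missing samples

Occasional single-sensor dropouts are imputed per channel by
chained-equation regression: for each contiguous gap, the channel is
regressed on time and the three synchronous channels of the *other* sensor
of the pair over a ±0.5 s observed window, and 50 posterior-predictive
draws are averaged (drawing both coefficients and residual noise).
Observed samples are never modified. If any sensor of a joint is missing
for ≥ 20% of samples the joint is flagged untestable: an untestable target
joint voids the trial, an untestable nontarget joint is dropped from the
IMS mean. Gaps with too little local context fall back to linear
interpolation.

### Reference contexts

Adult reference statistics are pooled over left/right target trials via
mirroring (contexts keyed by target joint type; nontarget joints keyed by
ipsi/contralateral relation × joint type), so each context is backed by the
full adult cohort. A strict per-(target, nontarget) mode is available
(`pooled=False`). Sample SDs use ddof = 1; a zero SD anywhere is a hard
error, as standardization would be undefined.

## Statistical battery

* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure, from the classical mean squares:
  `ICC = (MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)` with k = 2
  occasions. Variance components are reported as estimated; negative trial
  or error components are truncated to 0 (with a warning) only where the
  SEM is formed, because the SEM's square root requires nonnegative
  inputs and silent truncation inside the estimator would hide the
  degeneracy.
* **SEM and MDC** — `SEM = √(σ²_trial + σ²_error)`,
  `MDC95 = 1.96·√2·SEM`, and `MDC% = 100·MDC95 / grand mean` where the
  grand mean averages the test and retest means; MDC% is reported rounded
  to an integer. The *improvable fraction* is the share of participants
  whose baseline score minus the MDC95 does not cross 0 (the best possible
  score), i.e. who could demonstrably improve without a floor effect.
* **BCa bootstrap CIs** — subject-level resampling; bias correction from
  the fraction of replicates below the point estimate (with midrank
  handling of ties), acceleration from jackknife skewness. Forcing both
  corrections to zero reduces the interval exactly to the percentile
  interval, which is used as an algebraic closure test. If the statistic is
  undefined on more than 10% of replicates the CI is refused; if only the
  leave-one-out jackknife is undefined (tiny n), the acceleration falls
  back to 0 with a warning.
* **Rank correlations** — Spearman's ρ (Pearson on midranks) for summary
  scores, Kendall's τ_b (tie-corrected in both margins) for individual
  joints, where heavy tying is expected from 3-level clinical ratings.
  Magnitude bands: negligible ≤ 0.29, low 0.30–0.49, moderate 0.50–0.69,
  high 0.70–0.89, very high ≥ 0.90. ICC bands: poor < 0.50, moderate
  0.50–0.75, good 0.75–0.90, excellent ≥ 0.90 (half-open at the shared
  boundaries, which the verbal convention leaves ambiguous).
* **Robust ANCOVA** — a running-interval smoother: at each age design
  point (defaults 9.5, 12.5, 15.5 years) each group's local sample is
  every member within `span × MADN` of the point (span 0.7, MADN computed
  per group; MADN = MAD/0.6745). The local means (trim = 0; a trimmed mean
  is available) are compared with a percentile bootstrap of the difference
  (B = 2000), and the CIs are Bonferroni-adjusted across the design points
  (α/3 each), which keeps the family-wise null error at ≤ 5%. Windows with
  fewer than 5 members in either group are skipped with a warning. With
  span → ∞ and trim = 0 the procedure degenerates exactly to a plain
  bootstrap comparison of group means.
* **Wilcoxon signed rank** — systematic test/retest shift; exact
  distribution for ≤ 25 untied nonzero differences, normal approximation
  with tie correction otherwise.
* **Power** — the smallest detectable correlation solves
  `Φ(ncp − z_{α/2}) + Φ(−ncp − z_{α/2}) = power` with
  `ncp = √(n−3)·(atanh r + r/(2(n−1)))`, the Fisher-z approximation with a
  small-sample bias term; reported to two decimals. At n = 20, α = .05,
  power = .80 this gives 0.58.

## Synthetic data generator

No raw recordings of this kind are publicly deposited, so the simulator is
a first-class module that emulates the study design: 31 adults (18–50 y),
31 control children (6–18 y) and 20 patients (~8–17.4 y), each tested on
all six target joints at 50 Hz, patients twice (test/retest). Each
participant carries latent parameters:

| parameter | meaning | default (patients) |
|---|---|---|
| `sigma_track` | SD of avatar tracking error, screen units | lognormal, median 0.055 |
| `lag` | reaction delay, s | uniform 0.04–0.12 |
| `c_mirror` | coupling gain of the contralateral homologue | 0.26 × severity |
| `c_adjacent` | gain of ipsilateral neighbour joints | 0.16 × severity |
| `c_other` | gain of remaining joints | 0.06 × severity |
| severity | shared lognormal factor on all gains | σ = 0.6 |
| `fidget_sd` | baseline angular-speed noise, °/s | lognormal, median 1.0 |
| asymmetry | impairment multiplier on the more-affected side | lognormal, median 1.3 |

The target joint's angle is the inverse screen map of the path delayed by
the lag plus band-limited (≤ 0.3 Hz) tracking noise — tracking errors are
slow drifts away from the path, not sample-to-sample jitter. Nontarget
joints move as `gain × target excursion` (mirror coupling on the
contralateral homologue, adjacent coupling on ipsilateral neighbours) on
top of integrated band-limited fidget noise. Sensors are pure-gravity
accelerometers plus 0.02 g white noise, with 0.8% MCAR short dropout runs
per sensor; this keeps the angle inversion exact and testable. Control
children's coupling decays log-linearly with age (the maturation trend);
adults have near-zero coupling.

The behavioural realization of each trial is seeded per participant-trial
and *shared across occasions*; only the measurement layer (sensor noise,
dropouts) is redrawn at retest. Test-retest disagreement is therefore
controlled by one knob, `occasion_noise` (multiplicative lognormal
perturbation of the latent parameters at retest, default SD 0.15), plus
sensor noise — and setting `occasion_noise = 0` reproduces near-identical
score sets, a closure the tests exploit.

Synthetic comparator ratings are thresholded from the latent impairment:
SCALE (2/1/0 per joint) and GMFCS (I–IV) from a combined
tracking-plus-coupling index, the therapist's 0–3 involuntary-movement
count from the per-type gains (mirror, adjacent) and a latent trunk
variable that the six joint sensors deliberately cannot see. Trunk
movement is consequently *not* part of the IMS — the hardware description
has no trunk sensor — which mirrors how a therapist can notice movements
the instrument cannot.

Latent scales were chosen once so that default patient cohorts land inside
the descriptive ranges reported for this population (total accuracy
roughly 0.8–5, total IMS roughly 0.8–3 at the median, with a longer upper
tail for severe draws); they are study conditions, not tuning knobs.

### What the generator does not emulate

No multibody dynamics, muscle model, or linear-acceleration artifact; no
dystonic/ataxic movement phenotypes; no learning or fatigue across trials;
no trunk sensor. Passing tests therefore demonstrate that the *analysis
chain* is correct and sensitive under a plausible measurement model — not
that the instrument would behave identically on real children.

## Problem sizes and numerical choices

* Unit tests run shortened phases (5 s + 12 s) where only structure
  matters; closure and recovery checks use the full 25 s + 30 s design.
  Parameter-recovery checks use 50 simulated patients; the ANCOVA null
  check splits an 80-child control cohort into halves of 40, the smallest
  size at which the percentile bootstrap's local windows (~12–25 members)
  are near nominal coverage.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the full pipeline is a pure function of
  (config, seed) and emits a manifest sufficient to re-execute it.
* `filtfilt` is skipped for traces shorter than its padding requirement;
  degenerate inputs (zero-variance vectors, all-zero differences, empty
  smoother windows, zero reference SDs) raise or warn explicitly rather
  than returning silent NaNs.
* Bootstrap defaults: B = 1000 for ICC CIs, B = 2000 for the ANCOVA, both
  configurable.

## Known limitations

* The exact error norm and standardization used by the original
  instrument's software are not fully specified in the public description;
  RMSE and uncentered SD-standardization are the package's documented
  choices, with the centered variant one flag away.
* The 3 Hz low-pass plus 0.02 g sensor noise put a noise floor of a few
  deg/s under the movement metric; IMS differences between participants
  therefore understate small coupling differences (the floor is common to
  numerator and reference).
* MDC% is undefined for cohorts whose grand mean is ≤ 0 (possible for the
  uncentered IMS of very calm cohorts); the pipeline reports it as missing.
* The BCa interval can, by construction, exclude the point estimate in
  extreme skew; the result object flags this rather than repairing it.
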