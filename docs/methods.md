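# Methods

This note documents the models and procedures implemented in `vrgaze`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Study design being modelled

Five cultural samples view 30 static 3D scenes (2 training + 28 test)
for 4 s each, preceded by a 500 ms fixation cross, under a
free-viewing instruction. Sixteen test scenes place both focal objects
at equal distance from the viewer; twelve place one object closer and
one further. Gaze is recorded at 90 Hz with an estimated angular
accuracy of 0.84° and precision of 0.16°. The analysis unit is the
participant: mean focal-object dwell per 4-s trial over the 28 test
trials, and mean dwell on the closer- and further-placed object over
the 12 varied-distance trials.

## Scene model and gaze classification

Colliders are convex, watertight triangle meshes stored pre-inflated
(default scale 1.10 about the object centroid, the mean of hull
vertices). The inflation absorbs tracker inaccuracy at object
contours. Classification casts the cyclopean gaze ray (viewer head at
the origin, +z forward, meters) against each collider's half-space
representation; the smallest nonnegative entry distance wins, so
occlusion order is respected. Ties below 1e-9 m resolve
deterministically to the first object. Rays hitting no collider are
background; invalid samples are missing. The scaling center and the
occlusion tie-break are implementation decisions — the classification
contract only requires a total, deterministic labelling.

Coplanar hull facets are merged before ray tests (a box collider has 6
planes, not 12 triangles), which matters only for speed.

## Visit detection

Each 90 Hz sample carries the nominal inter-sample interval
1000/90 ≈ 11.11 ms; dwell is computed from sample counts, not raw
timestamp differences, so toy examples are exact and a fixed-rate
tracker is modelled faithfully (an actual-timestamp mode would be a
straightforward extension; the default pipeline never needs it).

Maximal same-label runs of valid samples form candidate episodes. Two
rules apply, **merge first, minimum-duration second**:

1. *Merge*: an episode on object X, a single run on another
   (non-missing) category strictly shorter than 32 ms, then X again,
   fuse into one visit. The interruption's own duration is **not**
   credited to the visit. Merging scans left to right, so chains
   X y X y X collapse into one visit.
2. *Minimum duration*: surviving episodes must exceed 50 ms strictly
   (the conventional threshold for cognitive registration); at 90 Hz
   the shortest surviving visit is 5 samples (55.6 ms).

Decisions worth making explicit:

- **Order of operations.** Merging before thresholding prevents an
  interrupted 2 × 30 ms look (60 ms genuinely on-object) from being
  destroyed, which matches the merge rule's purpose of absorbing
  momentary measurement error.
- **Interruptions are single original runs.** A sequence
  FO1 · FO2 · BG · FO2 · FO1 with every middle run short does *not*
  bridge the outer FO1 episodes: the material between them spans more
  than one category and ≥ 32 ms in total. Equivalently, a merged
  visit never itself acts as an interruption. The exhaustive detector
  tests pin this semantics.
- **Missing data never merge.** Any run of invalid samples terminates
  an episode; the merge rule is reserved for short hits on other
  objects.
- **Background is symmetric.** Background episodes form visits and
  participate in merging exactly like focal episodes.

Every sample is accounted to exactly one bucket — visit dwell,
rejected episode, interruption, or missing — and the suite asserts
this conservation identity exactly on every simulated trial.

Data loss per trial is (expected − valid) / expected samples with
expected = round(duration × 90/1000). Participant aggregation uses
exactly the 28 test trials (training excluded); a participant missing
any test trial is flagged incomplete rather than silently averaged.

## Synthetic gaze generator

The generator exists so every downstream stage is testable without any
data download; its defaults *are* the study conditions.

- **Participant level.** Focal dwell per trial is drawn once per
  participant from Normal(group mean, group SD) truncated to
  [0, 4000] ms. The five default group profiles carry the study's
  per-country means and SDs (e.g. Czechia 1547.14 (506.07) ms,
  Taiwan 687.81 (244.53) ms) and closer-minus-further deltas
  (−5.6 to +173.7 ms).
- **Trial level.** A two-state semi-Markov process alternates focal
  and background looks. State durations are shifted exponentials with
  a 100 ms minimum look; means are chosen on a cycle (≥ 1 s) so the
  expected focal fraction equals the participant's dwell fraction.
  The process starts in its stationary distribution to avoid onset
  bias. This is the simplest process with controllable expected dwell
  and realistic visit structure; it does not model saccade kinematics,
  vergence, or head motion.
- **Which object.** During focal states the ray aims at one object's
  collider center; in varied-distance scenes the closer object is
  chosen with probability ½ + δ/(2·dwell), which makes the expected
  closer-minus-further dwell equal the profile's δ.
- **Noise.** Accuracy error is a per-trial constant angular offset
  (uniform direction, Rayleigh magnitude with mode 0.84°); precision
  error is per-sample isotropic Gaussian jitter (SD 0.16°). Both are
  applied in the tangent plane of the aim direction.
- **Loss.** Samples drop independently at rate 0.004, and a blink gap
  (uniform 100–300 ms) occurs in 4% of trials; together these realise
  the study's reported ~0.6% average data loss.
- **Reproducibility.** One cohort seed fans out to per-participant
  child seeds keyed by participant index, so cohorts are bytewise
  reproducible and extensible.

What the generator does **not** emulate: fixation/saccade
microstructure, depth-of-fixation, scene semantics, or any real
within-participant trial-to-trial correlation (trial-level variance
comes only from the semi-Markov process, a free parameter of the
model, not an estimated one). Passing parameter-recovery tests
therefore shows the pipeline's arithmetic is right under the assumed
generative structure, not that the assumptions hold for real eyes.

The schematic default scene set places two 0.7 m box colliders at
±12° azimuth (equal scenes at 2.0 m; varied scenes at 1.5 m and
3.0 m) with the background aim 30° above the horizon; geometry is
chosen so collider solid angles (7–14° half-angle) dominate the ~1°
angular noise, keeping the measured dwell centred on the generative
target (verified by Monte-Carlo calibration tests).

## Quality control

The exclusion cascade runs in the study's order — technical failure,
mean data loss, failed validation, ADHD history — counting each
participant at the first stage that catches them. The loss threshold
is *strict* exceedance of 5%: exactly 5% is retained (the boundary is
underdetermined by the phrase "set at 5%"; strictness is the
conservative reading). The validation rating is consumed as a boolean
because the original is a qualitative two-rater judgment with no
published numeric criterion.

The depth-analysis outlier screen replaces visual QQ inspection with a
deterministic surrogate: standardized residuals from the group ×
object-type cell-means model, flagging |z| > 3.0. On synthetic
cohorts this recovers planted gross outliers and flags essentially
nothing otherwise.

## Statistics

- **Welch one-way ANOVA** from raw data or summaries (formulas in the
  README). ω² is reported from the classical decomposition
  (SS_b − df₁·MS_w)/(SS_t + MS_w) computed on the same data, because
  ω² has no canonical Welch form; both SS terms are exactly derivable
  from n/mean/SD, so summary mode reproduces it too.
- **Post-hocs.** p-values are Games–Howell proper: studentized range
  on the unpooled standard error with per-pair Welch–Satterthwaite
  df. Confidence intervals are the pooled-variance Tukey HSD
  construction. Published tables sometimes pair these two
  constructions, so both are emitted with explicit labels rather than
  guessing a single intent.
- **Hedges g** with the J = 1 − 3/(4n − 9) small-sample correction
  and large-sample normal CIs (within 0.01 of noncentral-t intervals
  at these group sizes).
- **Mixed ANOVA** (between groups × 2-level within factor) via the
  exact sum/difference decomposition: the group effect is the one-way
  ANOVA of subject means over MS subjects-within-groups; the within
  main effect tests the unweighted mean of per-group difference-score
  means (the Type-III convention of the R packages standard in this
  field, relevant only under unequal group sizes); the interaction is
  the weighted between-group effect of the difference scores.
  Sphericity is trivial with two levels. Per-effect
  ω² = df·(MS_eff − MS_err)/(SS_total + MS_subj). Omnibus p-values
  are Holm–Bonferroni adjusted as a family of three. Verified against
  an independent implementation to 1e-8 on balanced designs.
- **Simple main effects** per group: the paired closer-vs-further
  contrast (F = squared paired t, df (1, n−1)) with t-based CIs,
  generalized η² including subject variance in the denominator, Holm
  adjustment across the five groups.
- **ANCOVA** via an OLS fit with Type-II sums of squares and partial
  η²; constant covariates are dropped with a warning.
- **Power analysis**: smallest equal-group total N (divisible by k)
  whose noncentral-F tail beyond F_crit(α; k−1, N−k) with λ = f²·N
  reaches the target power. For f = 0.25, α = 0.05, power = 0.80,
  k = 5 this gives N = 200 (power 0.810; N = 195 achieves only
  0.798).
- Studentized-range probabilities come from scipy's numerically
  integrated distribution (tolerance well below 1e-6); fractional df
  are reported to two decimals.

## Problem sizes and tolerances

The test suite exercises the visit detector exhaustively on all label
strings up to length 10 plus 10⁴ random longer strings; parameter
recovery uses 50 replicate cohorts of 200 participants × 28 trials;
the Welch type-I calibration uses 2,000 simulated five-group null
datasets at the study's observed heteroscedasticity (rejection rate
required in [0.04, 0.06] at α = 0.05). Dwell arithmetic is exact to
float precision; conservation is asserted at 1e-6 ms; geometry
oracles march 2,000 points per ray.

## Known limitations

- The generator's trial-level variance is a modelling choice, not an
  estimate; only between-participant moments are matched to the
  reference profiles.
- Colliders must be convex; concave objects would need convex
  decomposition upstream.
- The two-rater validation protocol is irreproducible from the
  published description and is modelled as a planted boolean flag.
- Summary-mode verification is limited by the printed rounding of its
  inputs (±0.005 on means/SDs), which bounds agreement at roughly
  ±0.05 on the omnibus F.
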