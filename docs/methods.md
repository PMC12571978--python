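# Methods

## Task and coordinate conventions

The pointing task seats the participant on a swivel chair facing a 3 × 3
target matrix on a wall 192 cm away, eye level aligned with the center row.
All directions live in a right-handed room frame with origin on the chair's
rotation axis at eye height: +x toward the wall center, +y to the
participant's left, +z up.  Azimuth is the signed horizontal angle from +x
(positive leftward, range (−180°, 180°]); polar is the elevation above the
horizontal plane ([−90°, 90°]).  This puts the passive whole-body yaw
rotations entirely in the azimuth plane, which is what makes the
azimuth/polar split diagnostic: vestibular heading error can only appear
horizontally.

The physical spacing of the matrix is not critical for the analysis (scores
are deviations relative to per-participant calibrations, not absolute
angles), so it is configurable; the default of 51.4 cm horizontal/vertical
spacing puts the off-center targets at ≈15° eccentricity, typical for this
task family.  Angle arithmetic uses wrap-aware differences
(`a − b` mapped into (−180°, 180°]) and circular means for azimuths, so
nothing misbehaves near the ±180° branch cut even though real task geometry
stays far from it.

## Scoring

A session comprises two calibration paradigms — world-based (laser pointer
visualizes the vector on the wall) and retinotopic (eye–finger alignment) —
followed by five eyes-closed test paradigms: T1 initial reproduction, T2
rotated 90° to the non-dominant side, T3 back at start, T4 rotated 90° to
the dominant side, T5 back again.

* **Calibration references** per target: circular mean of trial azimuths,
  arithmetic mean of polars.  Calibration *quality* is the mean great-circle
  separation between the nine references and the true target directions
  (computed in the numerically stable chord form 2·arcsin(‖u−v‖/2)).
  Participants whose quality exceeds a threshold (default 10°) are excluded
  from scoring: typical calibration offsets sit well below that, so 10°
  separates ordinary inaccuracy from gross miscalibration (e.g. a
  misunderstood instruction).  The threshold is configurable.
* **Paradigm scores**: repeats are averaged within target first (so
  unbalanced repeat counts never reweight targets), then the signed
  per-target deviation from the reference is taken per plane.  The accuracy
  score is the mean of the nine absolute deviations (floor 0°); the spread
  is the sample SD (n−1) of the nine signed deviations.  Spread is computed
  on signed deviations per frame × plane — an alternative reading would
  compute it on raw vector coordinates, but the signed-deviation form keeps
  the metric in degrees, frame-specific and directly comparable to the
  accuracy scores.
* **Rotated paradigms (T2, T4) are scored against the same room-referenced
  calibration.**  The targets are static world objects; a correct response
  points at the remembered world position regardless of trunk orientation,
  so any uncompensated heading error surfaces as azimuth deviation.  This is
  the design decision that lets the post-rotation metrics carry the
  vestibular signal.
* **Aggregates**: overall = mean(T1..T5); reproduction = T1; transformation
  = mean(T2, T4); post-rotation = mean(T3, T5); strategy index = mean over
  paradigms of (retinotopic − world deviation) per plane, negative meaning
  predominantly egocentric encoding; disorganization = mean spread over
  paradigms per frame × plane.  Whether "transformation" and "post-rotation"
  each pool two paradigms is an interpretation (the rotated paradigms demand
  the mental transformation; the return paradigms test cumulative heading
  updating); the mapping is exposed in the scoring configuration so either
  reading can be produced.

## Synthetic cohort generator

No raw clinical data ship with the package, so a generative model produces
cohorts with the statistical structure the analysis assumes.  It is a
deliberately minimal construct — Gaussian noise throughout, linear
angle-space mixing — chosen so that every mechanism admits a closed-form
check.  Per participant:

* **Calibration trials**: world references = true angles + N(0, σ_cal) per
  trial; retinotopic references additionally carry a systematic offset
  (retino_bias_az, retino_bias_pol), the stand-in for eye–finger alignment
  bias.
* **Heading error**: rotation events precede T2..T5 with nominal signed
  magnitudes (−90°, +90°, +90°, −90°), mirrored for left-handers.  Event k
  contributes ε_k ~ N((1 − g)·90°·sign_k, σ_vest), where g is the vestibular
  gain (perceived/actual rotation) and σ_vest the per-event tracking noise.
  Accumulated heading error follows H ← (1 − ρ)·H + ε_k with H = 0 before
  T1.  ρ ∈ [0, 1] models partial re-anchoring at each paradigm change
  (whether participants regain an external heading cue between paradigms is
  not observable, so ρ is a parameter rather than a fixed fact; default
  0.5).  Heading error enters the azimuth only.
* **Test trials**: intended azimuth = w·retinotopic_ref + (1 − w)·world_ref
  + H_p, with w ∈ [0, 1] the encoding weight (1 = fully egocentric); polar
  analogous without H.  Measured = intended + N(0, σ_motor) per plane.
  Angles here are small (±16°), so convex combination in angle space is
  safe.

Group presets (HC: σ_motor 5°, σ_vest 2°, g = 1.0; PPPD: σ_motor 5.5°,
σ_vest 5°, g = 0.97; BVP: σ_motor 5.5°, σ_vest 8°, g = 0.9; between-subject
SDs on all parameters) are demonstration defaults that reproduce the
qualitative clinical pattern — post-rotation azimuth deviation ordered
BVP > PPPD > HC, effects confined to the azimuth plane — with the default
cohort of 32 BVP / 43 PPPD / 32 HC.  Validation of the generator is
*parameter recovery*, never resemblance to clinical means: with only motor
noise active, the scored mean absolute deviation must equal the half-normal
mean σ·√(2/π) within Monte-Carlo error; w = 1/0/0.5 with a nonzero
retinotopic bias must yield negative/positive/zero strategy index; σ_vest
must raise azimuth deviations monotonically and leave polar deviations
untouched.

Metadata (age, sex, questionnaire scores: MoCA, PHQ-9, SBSODS, EISOD with
four subscores, state/trait anxiety) are placeholder draws from truncated
normals with group-specific means matching the published cohort
descriptives.  They carry the *marginal* distributions only — the generator
does not model correlations between questionnaires and pointing parameters,
so cross-domain correlation analyses on synthetic data test plumbing, not
effect recovery.  Other aspects of real data the generator does not emulate:
reaction times, trial-order effects, fatigue, non-Gaussian motor error, and
any coupling between age and performance.  Passing tests therefore
demonstrate correctness of the scoring and statistics machinery under a
known model, not clinical validity of the presets.

Determinism: the master seed spawns per-participant substreams keyed by
cohort index (`SeedSequence(master, spawn_key=(index, stream))`), so editing
one group's size never perturbs draws for participants earlier in the
roster, and every output is byte-reproducible from config + seed.

One honest caveat: because the patient presets carry slightly larger motor
noise than controls (5.5° vs 5.0°), a *weak* polar group effect exists by
construction.  Paradigm-level polar ANCOVAs stay null at conventional
cohort sizes (as in the clinical pattern), but the five-paradigm polar
average, which halves the noise, can reach nominal significance in some
seeds.

## Statistical battery

* **ANCOVA**: linear model with treatment-coded group indicators plus
  covariates; the group effect is the partial F from comparing the full
  model against the covariates-only model (df1 = k−1, df2 = N−k−c).
  Adjusted group means are model predictions at covariate grand means.
  Constant covariate columns are dropped (they alias the intercept), which
  makes the ANCOVA reduce exactly to the one-way ANOVA; genuinely collinear
  designs raise an error naming the offending columns.
* **Post hoc contrasts**: default is a seeded stratified percentile
  bootstrap (B = 1000) of the pairwise adjusted-mean differences; each
  contrast's bootstrap SE feeds a studentized-range statistic
  q = √2·|Δ|/SE with family-wise p from the Tukey distribution (k groups,
  error df).  A fully analytic Tukey mode (model-based SEs) provides
  deterministic p-values for testing, and planned contrasts can be reported
  unadjusted.
* **Track selection**: Levene's test (mean-centered by default; median
  option = Brown–Forsythe) on the outcome across groups gates the analysis:
  p < 0.05 routes the outcome to Kruskal–Wallis (tie-corrected H, chi-square
  p) with Dunn's post hoc z-tests (standard tie correction
  T = Σ(t³−t)/(12(N−1)); Holm-adjusted by default, Bonferroni/none
  available).
* **Correlations**: Spearman's ρ with average ranks for ties, p from the t
  approximation, reported with Fisher's z = atanh(ρ).  Of the five published
  ρ/z pairs used as worked checks, three agree with atanh at two printed
  decimals; two differ by one unit in the second decimal (print rounding in
  the source), and one further pair carries a sign-inconsistent printed z
  and is not used.
* **Welch's t** (Satterthwaite df) handles two-group clinical-flag splits.
* **Power**: the a priori sample size searches balanced totals N (multiples
  of k) for the smallest with noncentral-F power ≥ target, using
  λ = f²·N, df1 = k−1, df2 = N−k at the level-α critical value.  For the
  study design (k = 3, f = 0.40, α = 0.05, power 0.95) this gives N = 102;
  an unbalanced (per-integer) search is available.
* **Calibration of the machinery**: under a simulated null (no group
  effect, a real covariate effect), the ANCOVA group test rejects at the
  nominal rate (checked over 500 replicates at N = 102 within two binomial
  SEs of α = 0.05).

All stochastic procedures take explicit seeds; reports record seed, B,
method labels, package version and a config hash.

## Numerical choices

* Degenerate inputs raise typed errors rather than returning NaN: zero-length
  direction vectors, constant vectors in correlations, all-identical data in
  Kruskal–Wallis (tie correction divides by zero), zero variance in both
  Welch groups, circular means with vanishing resultant.
* Residual sums of squares below a scale-aware epsilon
  (10⁻¹² · n · (max|y|+1)²) are treated as exactly zero so that identical
  outcomes yield F = 0 instead of numerical noise.
* The zenith/nadir azimuth is reported as 0° by convention.
* Angles serialize in degrees with six decimals; CSV dialects are UTF-8 with
  "." decimals and mandatory headers; a trials file must use exactly one
  direction representation (unit vectors or azimuth/polar pairs).

## Validation problem sizes

The shipped test suite works at sizes chosen to keep the full run fast while
leaving Monte-Carlo margins comfortable: ~10⁴ scored deviations for the
half-normal recovery (223 participants × 45 deviations), 1000 randomized
instances for the brute-force scoring oracle (tolerance 10⁻⁹), one full
default cohort (107 participants) for the qualitative-structure check, and
500 replicates for the type-I calibration.

## Known limitations

* The generator's heading-error recursion is first-order; real vestibular
  path integration shows velocity-storage dynamics it does not capture.
* The bootstrap/Tukey hybrid is one reasonable construction of an
  under-determined post hoc recipe; the analytic Tukey mode is provided
  precisely so results never hinge on the bootstrap variant.
* Strategy-index recovery is a sign/ordering property, not an unbiased
  estimate of w: motor noise attenuates the index toward zero.
* Questionnaire scores are placeholders with realistic marginals; analyses
  linking them to pointing behavior have no planted effect to recover.
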