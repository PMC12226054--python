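# Methods

## Task design

A session comprises 600 trials in six 100-trial blocks (defaults; both
configurable subject to divisibility). Participants classify a picture —
one of six categories: neutral, generic aversive, and four OCD-relevant
themes (symmetry, checking, hoarding, washing) — as negative or
non-negative within a 0–1500 ms response window; on 25 % of trials an
auditory stop signal instructs them to withhold the response. Within each
block every category appears `floor(100/6)=16` or 17 times; the four
categories receiving the 17th trial are drawn uniformly at random per
block, stop trials occupy exactly 25 uniformly random positions per block
(an exact count, not per-trial Bernoulli, which stabilizes staircase
tracking), and picture side is an independent fair coin. Trial events sit
on a common millisecond clock: enforced central fixation (200 ms), stimulus
onset, the stop tone at onset + SSD on stop trials, the response deadline
at onset + 1500 ms, then a 1000 ms inter-trial interval.

The stop-signal delay follows a 1-up/1-down staircase: start 250 ms,
+50 ms after each successful inhibition, −50 ms after each failed stop,
clamped to [0, 1200] ms — the ceiling keeps the tone inside the response
window with margin; no bounds are inherent to the procedure itself. One
global staircase serves all categories (per-category SSDs are recorded and
averaged per category at analysis time). When a session's stop-success rate
leaves the 40–60 % band, the quality-control report recommends enlarging
the step to 75 ms.

## Race model

Behavior is generated by the independent horse-race account of stopping:
the go process finishes after an ex-Gaussian time, `Normal(μ, σ) +
Exponential(τ)` (redrawn while non-positive; the truncation bias is
negligible at the defaults), and the stop process, when triggered, finishes
at SSD + SSRT_true. A response escapes iff the go time beats SSD +
SSRT_true, or the stop process fails to trigger at all
(`trigger_failure_prob`). Stop latency is a per-category constant — the
simplest model under which the integration estimator is unbiased; the
parameterization is written so variance could be added later. Failed-stop
(signal-respond) RTs are recorded but flagged and never enter go-RT
analyses.

Defaults: neutral go μ=450, σ=80, τ=100 ms with SSRT_true=180 ms; the five
aversive categories get +50 ms on μ and +65 ms on SSRT_true, so
category-mean SSRTs sit near 180 ms (neutral) and 245 ms (aversive) — the
magnitude of emotional interference the task is designed to detect.
Nuisance rates default to trigger failures 2 %, injected go omissions 1 %,
classification errors 5 % (field-typical values; classification
correctness is treated as independent of category, since what counts as a
"correct" valence response for an OCD-relevant picture is not
well-defined). `ParticipantModel.stationary()` builds the
identical-across-categories, nuisance-free participant used for estimator
validation.

## SSRT estimation

Per category: `p_fail` = responded stop trials / stop trials; `mean_ssd` =
mean SSD over that category's stop trials (a session-wide mean is available
as an option — the averaging scope is a genuine ambiguity and category-
specific is the default because each category's stop trials are what the
category's estimate conditions on); `RT_p` = the nearest-rank percentile
(1-based index `ceil(p·n)`, p=0 mapping to the minimum) of the correct-go
RT distribution after appending one copy of the maximum observed go RT per
go omission; `SSRT = RT_p − mean_ssd`. Incorrect classifications are
excluded from the go distribution. Nearest rank is the consensus
prescription for the integration method; the omission correction guards
against deadline censoring inflating fast percentiles.

Validation (in the test suite): over 50 seeded 600-trial sessions of a
stationary participant with SSRT_true = 200 ms, the mean estimate lands
within ±10 ms of truth; the staircase's mean stop success over 20 seeded
sessions lies in [0.45, 0.55]; the estimator is translation-equivariant.

## Gaze synthesis and analysis

Screen geometry is fixed at 1920×1080 px on a 475×267 mm active area (a
standard 22″ 16:9 panel; the physical size is a documented constant of the
toolkit) viewed at 60 cm; pixel↔degree conversion is linear (small-angle),
accurate to <1 % centrally. 1° ≈ 42.3 px. The picture AOI is the 800×600 px
image bounds centered at 8° left/right of screen center — at this geometry
the image rectangle overlaps screen center, so central fixations are
legitimately inside the AOI; metrics and ground truth both honor that.

Synthetic trials hold central fixation, saccade to the AOI after a
parameterized latency (default 180 ms ± 15 ms across trials) with a linear
30 ms travel, dwell (600 ms total, split over `1+refix_count` visits), and
return to center, sampled at 2000 Hz with isotropic Gaussian jitter
(default SD 2 px ≈ 0.05°, representative of a high-end video tracker's
noise floor). Ground truth per trial is computed from the constructed path
under the metric definitions themselves (which holds lie in the AOI, which
start after onset) — not by running the detector — so it stays an
independent oracle. Tracker loss is injected as contiguous blink-shaped
invalid runs (default blink 100 ms, with 20 ms half-cosine pupil ramps)
until the requested fraction is reached; the achieved fraction lies within
one blink length above the request.

Fixation detection is dispersion-threshold (I-DT): maximal windows of
valid samples whose x-range + y-range stays ≤ 1.0° and which last ≥ 100 ms;
invalid samples terminate windows; a fixation's end extends one sample
interval past its last sample so a k-sample hold has duration k·Δt. The
thresholds are exposed in the API/CLI. AOI membership is decided by
fixation centroid (half-open rectangle, origin top-left). Latency to first
fixation = start of the first in-AOI fixation beginning at/after stimulus
onset; a fixation already in progress at onset contributes its post-onset
portion to dwell but is ineligible as "first" (vigilance must follow
onset). Trials with no in-AOI fixation, or with strictly more than 25 %
invalid samples in the analysis window, are excluded (25.0 % exactly is
kept). Drift-check errors strictly above 1.0° flag recalibration.

On noise-free streams the detector recovers constructed latency within one
inter-sample interval plus the window-granularity slop (the time a saccade
spends within the dispersion threshold of its endpoints — travel_time ×
threshold_px / saccade_amplitude_px), and dwell within twice that; the
tests use near-instant saccades to pin this at the sample interval. With
realistic noise, occasional splitting of the long pre-onset central hold
can misattribute a "first fixation" when the AOI contains the center; this
is a genuine fragility of first-fixation latency under overlapping AOIs,
not a detector defect.

What the synthetic streams do **not** model: saccadic main-sequence
kinematics, microsaccades, smooth pursuit, calibration drift, and gaze
during the inter-trial interval (streams span fixation onset through the
response deadline). Passing recovery tests therefore demonstrates the
correctness of the parsing/metric pipeline, not robustness to oculomotor
phenomena absent from the generator.

## Statistical workflow

`paired_test` is the classic paired t on differences with Cohen's
d = mean(diff)/SD(diff); Shapiro–Wilk on the differences is reported as a
flag and never switches the test. All-zero difference vectors return
t = 0, d = 0 (identical inputs); constant nonzero differences raise an
error since t is undefined.

`rm_anova` implements the univariate split-plot decomposition (Condition
within, Group between): between-subject SS split into Group and
Subject-within-Group error; within-subject SS into Condition,
Condition×Group and Condition×Subject-within-Group error; partial η² =
SS_effect/(SS_effect+SS_error). Greenhouse–Geisser ε and Mauchly's W are
computed from the pooled group-centered covariance (error df N−k);
Mauchly's p uses Box's chi-square approximation with the second-order term,
following R's `mauchly.test` coefficients. When ε < 0.75 the within-effect
dfs are multiplied by ε (the reported df are the adjusted ones); the Group
test is unaffected. The decomposition is cross-checked against
`pingouin.mixed_anova` in the tests (F, p, df, η² agree to machine
precision; Mauchly's p to <0.1 %, the residual being pingouin's variant
second-order coefficient). Balanced groups are expected; unequal group
sizes use weighted (size-proportional) condition means.

Trait correlations are Pearson r over all trait×metric pairs computed in
one call, Bonferroni-corrected with the family = the number of defined
correlations in that call (constant columns are flagged undefined and
excluded from the family). The symptom-targeted analysis correlates each
OCI-R subscale (symmetry, checking, hoarding, washing) with the SSRT of
its matching category only.

Sample size for the within-between interaction uses the noncentral F with
λ = f²·N·m·ε/(1−ρ), df₁ = (k−1)(m−1)ε, df₂ = (N−k)(m−1)ε — the convention
of the G*Power program, adopted deliberately so results are comparable
with the tool this field actually uses; other conventions (e.g.
λ ∝ N·f² without the m·ε/(1−ρ) multiplier) give different Ns, which is
worth knowing when diagnosing discrepancies. The search returns the
smallest N that is a multiple of k with power ≥ target. At the default
spec (f=0.25, α=0.05, power 0.95, k=2, m=6, ρ=0.5, ε=1) this is N=28
(achieved power 0.954; N=26 reaches only 0.936).

The ANOVA's null calibration is verified by simulation: 1000 i.i.d.
Gaussian replicates at the design's dimensions give a Condition rejection
rate of 0.05 ± 0.02.

## Cohort simulator

`simulate_cohort` generates subject-level tables (long SSRT table, wide
per-category SSRT, gaze-metric summaries, questionnaire totals and OCI-R
subscales) from a parametric model: subject random intercept (SD 40 ms),
condition effects (default +65 ms for aversive categories), group effect
(default +30 ms for the clinical group), optional group×condition
interaction and an optional symptom-coupling slope (ms per SD of subscale
score) tying each OCD category's SSRT to its matching OCI-R dimension.
Residual noise SD is 30 ms. It deliberately skips trial-level simulation
so Monte-Carlo checks of the statistics stay cheap; it is not a substitute
for the trial-level race model when the estimator itself is under study.

## Problem sizes and numerical choices

Validation suites run at the study's native scale — 600-trial sessions,
20–50 seeds for staircase/SSRT recovery, 1000 ANOVA null replicates,
randomized gaze streams up to 2000 samples against a brute-force detector
oracle — sizes chosen to make the Monte-Carlo standard errors comfortably
smaller than the tolerances they check. Ties and degenerate inputs:
percentile p=0 maps to the minimum; QC band bounds are inclusive while the
loss and drift thresholds are strict; empty fixation lists are a valid
analysis result but empty go-RT sets or zero stop trials raise explicit
errors; schedule, simulation and synthesis are deterministic functions of
(config, seed) with a single generator threaded through each stage.

## Known limitations

- The race model's constant stop latency understates real SSRT
  variability; trigger failures are generated but not estimated.
- First-fixation latency is fragile when the AOI overlaps the enforced
  fixation point (see above); studies wanting a clean vigilance measure
  should use AOIs or eccentricities that exclude the fixation cross.
- The split-plot ANOVA assumes a complete, balanced within-subject design;
  missing cells are an error rather than being imputed.
- The ASC-subset dialect is a deliberate reduction; converting vendor
  exports requires keeping only header/MSG/sample lines and the four
  event labels.
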