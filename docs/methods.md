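# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want to
know about.

## Analysis units and aggregation

The analysis unit throughout is a *tested body side* of a subject
(subject × side), because the assessment is administered to both sides
where possible. Per-trial metric values (up to 5 repetitions × 9 pegs per
side and session) are collapsed to one value per subject × side × session
by the grand median across pegs and repetitions; even-length groups use the
mean of the two middle order statistics, and missing trials are simply
absent (no imputation). Reliability statistics use only units with complete
test/retest pairs.

## Confound model (selection step 1)

Each metric is first Box–Cox transformed. The transform is fitted by
profile log-likelihood over a λ grid [−3, 3] in steps of 0.01; values ≤ 0
are shifted by |min| + ε beforehand. Fitted transforms carry the Jacobian
normalization `scale = gm^(1−λ)` (gm = geometric mean of the training
values). This anchors the slope of the transform to 1 at the geometric
mean, so transformed values stay in the metric's own units and regression
coefficients remain comparable across the λ values fitted on different
samples — without it, the sampling jitter of λ̂ rescales every coefficient
and confidence interval by an arbitrary factor. The normalization cancels
everywhere downstream (it is an affine map), and the transform remains
exactly invertible.

In transformed space, intact-cohort values are modelled as

    y = β0 + β1·age + β2·sex + β3·tested side + β4·handedness
        + β5·stereo deficit + W_subject + ε

with a subject random intercept (both sides of a subject are correlated)
fitted by maximum likelihood. Categorical coding: male = 0 / female = 1,
left = 0 / right = 1, handedness = 1 when the tested side is the dominant
one, booleans false = 0 / true = 1. Covariates that are constant in the
sample are dropped with an explicit flag; cohorts in which every subject
contributes a single side fall back to OLS with a `no_random_effect` flag.

The fitter profiles β and σ² out of the likelihood and optimizes the single
variance ratio τ²/σ² numerically (bounded scalar optimization on the log
ratio, tolerance 1e−10). It agrees with a general-purpose mixed-model ML
fit to ~1e−6 and runs in about a millisecond, which is what makes the
parametric bootstrap below affordable. Standard errors are the usual GLS
ones at the ML variance estimates; with ~120 subjects their CIs cover at
roughly 92 % for a nominal 95 % (ML variance components are slightly
anticonservative), which is the expected finite-sample behaviour.

Confound significance uses a parametric-bootstrap likelihood-ratio test:
data are simulated under the reduced model (new random intercepts and
residuals at the reduced fit's variance estimates), both models are refitted
per replicate, and p = (1 + #{LR* ≥ LR_obs}) / (1 + B). The LR statistic is
one-sided by construction; B defaults to 1000 (configurable; the
stereo-vision rule is the only one that gates selection, at α = 0.05).
Non-converged replicates are redrawn and counted.

Model quality is summarized by C1 = 100·MAE/range and
C2 = 100·(MAE + 3σ)/range, computed in original metric units after
back-transforming fitted values (fixed effects plus the BLUP subject
intercept — the model's residual excludes the subject effect, which is part
of the model, not an error). The 5 % largest absolute residuals are
trimmed first (keep = ⌊0.95·n⌋); σ is the sd (ddof = 1) of the remaining
absolute residuals. A metric passes with C1 ≤ 15 and C2 ≤ 25; metrics
significantly influenced by stereo-vision deficits are removed regardless.

## Normalization

Confound removal subtracts only the covariate terms β1…β5·x in transformed
space — not the intercept and not the random effect — so the correction is
deliberately not idempotent. Corrected values are standardized as
ŷ = (ȳ − median_intact)/MAD_intact (raw MAD, no 1.4826 consistency factor),
sign-aligned using each metric's declared `worse_direction` so that higher
always means worse, and finally divided by the maximum over the affected
population and expressed in percent: the currently worst-performing
affected unit scores exactly 100 %. A metric with zero intact MAD, or whose
affected population never exceeds the intact median, is flagged degenerate
and excluded. The abnormality cutoff is the 95th percentile of normalized
intact values (imposed 5 % false-positive rate).

## Clinimetric scores (selection step 2)

* **AUC** — probability that a random affected unit looks worse than a
  random intact one (Mann–Whitney identity, ties ½); computed on the
  normalized scale, so orientation is already uniform.
* **ICC(A,k)** — agreement ICC from the two-way ANOVA of the n × 2
  test/retest matrix with both sides pooled:
  (MS_rows − MS_err)/(MS_rows + (MS_cols − MS_err)/n).
* **SRD** — 1.96·√2·Σ·√(1−ICC) with Σ the sd over all subject × side ×
  session values of the retest cohort (trial-level variance is already
  collapsed by the grand median); SRD% expresses it relative to the range
  of normalized intact values.
* **η** — 100·mean(retest − test)/range, with a two-sided paired t-test
  reported alongside (negative η = better scores at retest, i.e. task
  learning).

Pass criteria: AUC ≥ 0.7 and ICC ≥ 0.7 (both inclusive — the published
survivor set retains a metric printed at exactly 0.70), SRD% strictly below
its 80th-percentile cutoff, η strictly above its 20th-percentile cutoff.
The cutoffs are recomputed from the full evaluated metric set (including
the noise control) under the nearest-rank convention — the ⌈p·n/100⌉-th
order statistic, which reproduces the published η cutoff of −6.35 exactly;
linear interpolation is available via configuration. On the published
77-row table nearest-rank gives an SRD% cutoff of 30.20 where the original
analysis printed 30.3 (an interpolating percentile); every cutoff in
(28.93, 30.63] selects the same survivors, so the choice is immaterial to
the outcome.

## Redundancy reduction (selection step 3)

Metrics are rank-transformed and the partial correlation of each pair given
all remaining metrics is computed from the precision matrix of the rank
correlation matrix (a residual-regression implementation is kept as an
independent cross-check; they agree to 1e−8; near-singular matrices get a
documented ridge of 1e−10 with a flag). The pair with the largest
|ρ_p| ≥ 0.5 loses its lower-priority member; the matrix is recomputed after
every single removal (a batch mode exists) until no pair reaches 0.5.
Priority is the lexicographic psychometric order (AUC desc, ICC desc, SRD%
asc), with name order breaking exact ties, plus a manual-override list that
reproduces the two documented literature-preference removals of the
published analysis. Correlation strengths are labelled on the conventional
bands (very high ≥ 0.9, high ≥ 0.7, moderate ≥ 0.5, low ≥ 0.3, else very
low).

## Structural validation

KMO is the standard ratio of summed squared correlations to summed squared
correlations plus squared anti-image partial correlations. Parallel
analysis compares the eigenvalues of the observed correlation matrix with
those of simulated standard-normal data of identical shape and counts the
leading run of observed eigenvalues above the simulated threshold. The
default threshold is the 95th percentile of the simulated eigenvalues
rather than their mean: with the mean criterion, pure noise exceeds the
threshold for the first eigenvalue about half the time by symmetry, so the
mean rule cannot keep k = 0 on structureless data; the percentile rule
does, and both remain selectable. Factor extraction is maximum-likelihood
common factor analysis followed by promax rotation; factor sign
indeterminacy is resolved by making the largest-magnitude loading per
factor positive, loadings with |λ| ≥ 0.5 define the strong-assignment map,
and a uniqueness collapsing toward zero (Heywood case) is flagged, not
fatal.

Disability subgrouping: stroke by FMA-UE (ceiling = 66, mild 54–65,
moderate 35–53), MS by ARAT (full 55–57, notable 43–54, limited 22–42),
ARSACS by age (young 26–36, mid 37–47, older 48–58). Scores outside all
bands (e.g. FMA-UE < 35) are labelled `unclassified` with a warning and
excluded from the banded comparison. Each core metric is tested with a
Kruskal–Wallis omnibus (Bonferroni-corrected across metrics) followed, when
significant, by pairwise two-sided rank-sum tests Bonferroni-corrected
across pairs; groups with fewer than two members are excluded with a
warning.

## Trajectory metrics

Recordings (`t, x, y, z, grip_force, active_peg[, fz]`, nominally 1 kHz)
are resampled to a uniform grid (linear interpolation bridges dropouts
longer than 50 samples; the active-peg indicator uses previous-sample
hold). A 1-D distance trajectory d(t) is the cumulative path length of the
filtered 3-D position; every signal is low-pass filtered with a zero-phase
4th-order Butterworth at 8 Hz before and after each time derivative
(velocity = d′, jerk = d‴; grip-force rate likewise).

Phase segmentation is event-driven: pickups and insertions are the rising
and falling edges of the active-peg indicator (a peg is lifted while the
grasp force exceeds 2 N). Within a lift, the transport is the ballistic
portion — from the last crossing below 10 % of the segment's peak speed
before the peak to the first crossing after it — and the hole approach runs
from transport end to insertion; the return and the next peg approach are
segmented the same way between insertion and the next pickup. Force buildup
and release are the contiguous intervals around the maximum and minimum
grip-force rate between approach and insertion (10 % prominence bounds).
The 10 % speed threshold is this package's stated approximation of
"ballistic onset"; on scripted minimum-jerk recordings the detected
boundaries sit within ~5 ms of the analytic ground truth.

Per phase: dimensionless jerk ∫j²dt·T⁵/L² and its natural log; SPARC (arc
length of the amplitude-normalized magnitude spectrum of the speed profile,
20 Hz ceiling, 0.05 adaptive amplitude threshold, zero-padding level 4 —
the published defaults); number of velocity peaks (local maxima with
prominence ≥ 5 % of segment peak speed); time/distance to peak velocity as
fractions of segment duration/path; path length ratio = chord/path, which
is ≤ 1 by construction because both use the same filtered positions;
throughput (D/W)/T with W = 2× the 3 mm alignment tolerance (the Shannon
form log₂(D/W+1)/T is a flag); mean/max trajectory error versus the
straight line; initial movement angles at 20 % of the straight distance, of
the covered path, and at peak speed; summed horizontal position error
during approaches (sample-rate dependent by definition, as a sum); grip
force mean/max, grip-force-rate mean/max absolute value, rate extrema
count, rate SPARC, buildup/release durations; vertical collision force
mean/max where an interaction-force channel is present; movement
onset/end counts, dropped pegs (grasp force dipping below 2 N and
recovering while a peg is lifted — the terminal release is the insertion),
and task completion time (first transport onset to last insertion).
Trial-level counters attach to peg 1 when converted to observation rows.

Known numerical sensitivities: the T⁵ factor makes dimensionless jerk the
most sensitive metric to one-sample boundary differences (≈5 % between
1 kHz and 250 Hz versus <2 % for the other smoothness and speed metrics),
and near-zero metrics (trajectory error of a straight movement) are
dominated by filter edge effects.

## Synthetic-data generator

The cohort generator emulates the *statistical* structure the pipeline
assumes, not disease-specific movement signatures. Per metric, a latent
value per subject × side × session is

    z = intercept + β·x·s + scale·(W_subject + trait_unit
        + shift_session·[retest] + e_session)

with var(W) + var(trait) = 1 (subject share `subject_tau2`, default 0.5),
`latent_scale` = 0.2 (a realistic log-scale dispersion for movement-
duration-like metrics; it also yields confound models of "moderate/good"
C1/C2 quality for metrics planted as good), and the observed value is the
inverse Box–Cox of z (`link_lambda` = 0, i.e. log-normal observations, by
default). Planted parameters map to population quantities analytically:

* ICC(A,2): session noise variance σ_w² = 2(1−ICC)/ICC − shift²/2;
* AUC: affected severity shift δ = Φ⁻¹(AUC)·√2·√(1+σ_w²) (binormal
  identity), applied post-transform;
* η: the session shift (in latent units) divided by the realized normalized
  range;
* factor structure: optional loadings replace part of the unit trait with
  common factors shared across metrics of a unit.

Demographics mirror the reference study (120 intact subjects, both sides,
first 60 retested; 53/28/8 affected with FMA-UE/ARAT/NHPT scores drawn
around the reported medians; ~90 % right-dominant, ~10 % stereo deficits).
Trial-level rows add N(0, trial_sd²·scale²) noise around the unit value.
The pure-noise control metric is drawn log-normally with mean 46.0 and sd
32.2 *of the variable itself* (log-space parameters derived analytically),
independently per unit and session — it mimics a total-time distribution
but carries no subject signal.

What passing tests on these cohorts show: the estimators recover planted
ICC/AUC/β at the study's sample sizes, the selection steps rank planted
signal above planted noise, and the factor machinery recovers planted
structure. What they do not show: behaviour under real-data pathologies —
heavy-tailed residuals beyond the log-normal, floor/ceiling-bounded
metrics, missingness correlated with severity, or disease-specific
kinematic signatures.

The recording generator builds minimum-jerk segments between board
waypoints, sigmoidal grasp/release force profiles crossing the 2 N
threshold exactly at the scripted times, optional sub-threshold force dips,
and optional corrective submovements — slow (~3 Hz content, surviving the
8 Hz filter) perpendicular out-and-back bumps in the deceleration tail,
which strictly worsen SPARC and dimensionless jerk and add velocity peaks.
Ground-truth phase intervals are the analytic 10 %-of-peak-speed crossings
of the noise-free profiles.

## Problem sizes and defaults in the shipped checks

The test suite and `scripts/acceptance.py` run the stochastic checks at the
reference design (120/60/89 subjects, 5 × 9 trials) with 60–150 replicates
per property and 99 bootstrap iterations per LRT — sizes chosen so the full
battery completes in a few minutes on one CPU while the Monte-Carlo error
stays well inside each property's tolerance. The pipeline default for the
bootstrap LRT remains 1000 iterations.

## Known limitations

* No beta-regression path for doubly-bounded metrics; their Box–Cox models
  legitimately fail C1/C2 and are removed.
* ML (not REML) variance components: fixed-effect CIs are mildly
  anticonservative at n ≈ 120 subjects.
* The η and SRD% cutoffs are relative (distribution-derived); with few
  evaluated metrics they necessarily discard the worst ~20 % even when all
  candidates are good.
* Segmentation thresholds are approximations validated only against the
  generator's ground truth, not against manually labelled real recordings.
* The published factor solution of the real cohort is not reproducible
  without the original data; factor-analysis correctness is validated on
  planted synthetic structure instead.
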