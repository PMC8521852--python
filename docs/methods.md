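# Methods

This note records the modelling choices behind `wearday`: what the
synthetic cohort emulates, how each analysis stage is operationalized, the
parameters that matter, and what the package's tests do and do not
establish about real hearing-aid data.

## The data model

A *day of use* is an 18-vector of minutes of hearing-aid use for clock
hours 6:00–23:59. Raw logs are long-format rows
(user, date, hour, ear side, minutes, connection flag) plus a table of
disconnection windows, each carrying the device counter's total minutes of
use during the window. All downstream analysis operates on the day matrix
**A** (days × 18), the user proportion matrix **B** (users × day types)
and the average-day matrix **D** (users × 18).

## Synthetic cohort generator

Real wear-time logs from connected hearing aids are proprietary, so the
generator produces cohorts whose structure matches what has been reported
for such data, with full ground truth (user group, per-day day type,
window positions and counters).

**Archetypes.** Three template day shapes, in minutes/hour over hours
6–23:

| archetype | shape | total |
|---|---|---|
| `full_day` | 30 at h6, 55 for h7–21, 30 at h22 | ~14.5 h |
| `afternoon` | 55 for h11–21, 30 at h22 | ~10.6 h |
| `sporadic_evening` | 40 for h18–20 | 2 h |

A fourth "atypical" day is flat-uniform noise on [0, 60] per hour,
emulating the ~3% of days with no recognizable pattern.

**Day-to-day variability.** No distributional form is reported for real
day-to-day variation, so the following are module conventions: onset
jitter shifts a day's active period by a whole number of hours
(Normal(0, 1 h), rounded); duration jitter extends or truncates the tail
(Normal(0, 1 h), rounded); hourly noise Normal(0, 5 min) applies to active
hours only, so unworn hours stay exactly zero; everything is clamped to
[0, 60]. The right ear is the left plus Normal(0, 2 min) per active hour,
exercising binaural resolution without creating artificial asymmetries.

**Users.** Group shares default to (0.494, 0.154, 0.198, 0.154) for
A/B/C/noise, the relative sizes reported for real cohorts of this kind.
Days per user are Normal(28.5, 18), clipped at 1 — users drawn below 10
days are later dropped by the preprocessing filter, as in real data. Each
user's day-type mixture is Dirichlet with mean putting 0.60 on the group's
predominant archetype (0.20 on each other) and concentration 10; noise
users draw from Dirichlet(1, 1, 1). Concentration 10 gives the dominant
component an SD of ~0.15 — groups overlap, which is what makes the
density-based user clustering non-trivial.

**Disconnections.** Each day independently receives at most one window
(rate 0.05) of 1–4 hours uniformly placed in 6–23; with probability 0.5
the window is rewritten as full-time use before masking. The counter
records the binaurally-resolved minutes inside the window exactly, so the
imputation path is conservation-testable. Windows of 3–4 on-off hours
exist deliberately: they exercise the day-removal filter.

**What the generator does not emulate:** weekday/weekend structure (a
weekend multiplier hook exists but is off by default, matching the
negligible association found on real data), seasonal drift, battery or
program usage, device loss, and the 10-minute raw telemetry stream —
generation is hourly because the analysis is.

## Preprocessing

Binaural resolution takes the per-hour maximum of the two ears; an absent
ear defers to the present one; hours absent on both sides count as zero
use and are tallied in the audit. Imputation per window: counter equal to
the window capacity (60 min × hours) → each hour gets 60 and the window is
flagged `full_time`; anything less is `on_off` and spread evenly, keeping
fractional minutes so totals are conserved exactly. Imputation runs per
resolved day; the per-ear-then-maximum order is interchangeable here
because windows mask both ears identically.

Filters apply in a fixed order: (1) any single on-off window strictly
longer than 2 h removes the day (full-time windows of any length are
kept — they carry no pattern ambiguity); (2) any hour above 60 min marks
malformed input; (3) total use below 60 min (a day with exactly 60 min is
kept); (4) hours outside 6:00–23:59 are excluded at construction; (5)
users left with fewer than 10 days are dropped entirely, judged on their
analyzable days, which is why this rule runs last. The audit records
counts per rule; filtering is idempotent.

## Amount-of-use statistics

Per-user mean daily hours and within-user SD use the sample (n−1)
denominator. Quartiles use linear interpolation. Segment contrasts are
pooled-variance two-sample *t*-tests with pooled-SD Cohen's *d* (the
classical "independent samples" reading; Welch is a one-line switch). The
variability curve is a least-squares fit of within-user SD on
(x, x²) with no intercept, since the relationship passes through the
origin (a user with zero use has zero SD); R² is computed against the
zero-prediction baseline, the convention consistent with through-origin
fitting. The curve maximum sits at −b₁/(2b₂) when b₂ < 0.

On default synthetic cohorts the fitted curve is reliably concave with its
peak near 8 h, and heavy users are markedly more consistent than medium
users. The lighter-users-also-more-consistent pattern seen in real data is
*not* reproduced: with these archetypes the variability peak falls inside
the light segment, so light and medium users show similar within-user SD.
Passing tests therefore establish the pipeline's arithmetic and the
concavity recovery, not the real-data segment ordering.

## Day-type clustering

Features are raw minutes/hour, unscaled — all 18 columns share units and
comparable ranges, and scaling would distort the total-use axis that
separates the archetypes. k-means uses k-means++ seeding with 10 restarts;
the seed is part of the configuration.

**Elbow rule.** The WSS/TSS curve is computed for k = 1…8. A candidate k
qualifies when the next marginal decrease falls below half the decrease
just achieved (adding a cluster stops paying off); among qualifying
candidates the *sharpest kink* — the k maximizing the ratio of successive
decreases — is chosen. A smallest-qualifying-k rule was considered and
rejected: on curves with one dominant first drop it terminates at k = 2
even when the k = 3 kink is visibly sharper, contradicting the visual
elbow judgment the rule is meant to formalize. The threshold (0.5) and the
full curve are exposed for manual override. Flat curves return k = 1 with
a warning.

**Silhouette.** Pairwise distances are quadratic in the number of days, so
the profile accepts an optional uniform subsample (default 5,000 rows in
the pipeline); coefficients are exact for the sampled rows.

**Outlier trimming.** "Abnormally distant" days are operationalized as
distance to the own-cluster centroid outside the closed interval
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] of that cluster's distance distribution. The
closed interval keeps clusters of identical points intact; the lower fence
is retained for symmetry though it is rarely active. This is an
interpretation — the distance definition could equally be to medoids or
k-nearest neighbors — and is isolated in one function.

**Naming.** For k = 3 the cluster with the smallest centroid total is
`sporadic_evening`; of the remaining two, the one with morning
(7:00–10:59) mass is `full_day`, the other `afternoon`. Any other k gets
generic names. Cramér's V uses √(χ²/(n·min(r−1, c−1))) on the
weekend × day-type table with no continuity correction.

## User clustering

**B** rows are proportions of *retained* typed days (post-trimming
denominators); users with no retained day are dropped with an audit entry.
Correlation distance between proportion rows is 1 − Pearson r of the
centered 3-vectors; a constant row (all components exactly 1/3) has
undefined correlation and is assigned distance 1 to everything. Note that
on the 3-simplex correlation distance is scale-free along rays: users with
the same *direction* of imbalance but different strengths are close, which
makes the density method segment by behavioral direction rather than
intensity.

The density-hierarchical method's minimum cluster size is expressed as a
cohort fraction (default 1000/15905 ≈ 6.3%) so cohorts of any size face
the same geometry. Internal metrics for the density method are computed on
non-noise points only; with noise included the scores would not be
comparable across methods. Winner selection counts metric-wise wins
(higher silhouette, lower Davies-Bouldin, higher Caliński-Harabasz) and
breaks three-way ties by silhouette; it is order-invariant.

A known, quantified property of the density winner: because it labels
low-dominance boundary users as noise, the *cluster cores* it keeps
average a higher predominant-type proportion (~64–66% on default cohorts)
than the cohort-wide generative expectation (60%). The partitioning
methods measure ~63% on the same cohorts. Consumers comparing recovered
group profiles against generative parameters should account for this
selection effect.

## Ensemble validation

The target is four-class (groups A/B/C plus the noise group) — the noise
users are real users the clustering declined to group, and a useful
classifier must recognize them. Inputs to the regression and the network
are standardized with train-split statistics; the trees see raw minutes.
Hyperparameters are fixed (no tuning): logistic regression with L2 and
newton-cg; 100 boosted trees of depth 5, γ = 0, L1 weight α = 0.1; the
network 18→128→64→32→4 with ReLU, cross-entropy and Adam for 25 epochs
(a training budget, not a convergence criterion — the non-convergence
warning is deliberately suppressed). The best individual classifier is
designated by held-out accuracy and breaks three-way disagreements.
Ensemble probability scores for ROC analysis are the unweighted mean of
the three classifiers' class probabilities. The 80/20 split is stratified
by class and seeded.

## Problem sizes and determinism

Default test and reproduction sizes are chosen so the statistics are
stable: ~20,000 days (850 users) for elbow recovery, ~30,000 days (1,200
users) for day-share recovery, 2,000 users for user-level recovery and
validation. Every stochastic step — generation, k-means restarts, the
HDBSCAN-adjacent distance computations, the split, the network — is
seeded, and the pipeline manifest content-hashes every output file so a
re-run with the same configuration must reproduce identical hashes.

## Known limitations

- All generator distributions (jitter forms, disconnection placement,
  binaural perturbation) are conventions, not fits to device telemetry;
  recovery results certify the pipeline, not any real cohort.
- The outlier-trimming and elbow formalizations are two of several
  reasonable readings; both are isolated behind single functions and
  configurable.
- Day-filter composition effects and the density method's core-selection
  bias shift recovered shares/proportions by 1–5 points relative to
  generative parameters (quantified above and in the test suite); analyses
  of real data inherit the same biases.
- No timezone or daylight-saving handling; dates are naive ISO-8601 days.
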