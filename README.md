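# wearday

Clustering of longitudinal hearing-aid wear-time logs: typical **day
types**, **user groups**, and a classifier-ensemble validation of the
grouping.

Smartphone-connected hearing aids log objective minutes-of-use per clock
hour, replacing unreliable self-report. Given months of such logs for a
cohort, audiology researchers want to know *how much* the devices are worn,
*when* during the day, and whether users fall into stable behavioral
groups. `wearday` implements that analysis end to end for hour-resolved
usage logs, together with a synthetic cohort generator with known ground
truth, so every stage is testable without access to proprietary device
data.

## The analysis

1. **Preprocessing.** Binaural logs are resolved per hour by taking the
   larger of the two ears. Hours lost to temporary disconnections are
   reconstructed from per-window minute counters: full-time use
   (counter = 60 min/h) is assigned directly, on-off use is spread evenly
   (60 min over 2 h → 30 min/h). Five filters then apply: days with an
   on-off disconnection longer than 2 h, malformed days (> 60 min/h), days
   with under 60 min total use, hours outside 6:00–23:59, and users with
   fewer than 10 retained days. The result is the day matrix
   **A** (r × 18), aᵢⱼ = minutes of use on day *i* during clock hour *j*.
2. **Amount of use.** Pooled and per-user daily hours, within-user SD,
   light/medium/heavy segments at the quartiles of per-user means,
   pooled-variance *t* contrasts with Cohen's *d*, and a no-intercept
   quadratic fit *y = b₁x + b₂x²* of within-user SD on mean use.
3. **Day types.** k-means (k-means++ seeding) on rows of **A**; *k* chosen
   at the elbow of the WSS/TSS curve; silhouette and 2-component PCA for
   evaluation; per-cluster outlier trimming at the Q1 − 1.5·IQR /
   Q3 + 1.5·IQR fences of the distance-to-centroid distribution; clusters
   named *full_day* / *afternoon* / *sporadic_evening* from their
   centroids; χ² + Cramér's V for the day-type × weekday association.
4. **User groups.** Each user becomes a row of **B**: the proportion of
   their retained days in each day type. Four clusterings are compared —
   k-means, Ward/Euclidean and average-linkage/Pearson-correlation
   agglomerative, and hierarchical density-based clustering (HDBSCAN,
   noise label −1) — scored by silhouette, Davies-Bouldin and
   Caliński-Harabasz; the method winning the majority of metrics is kept.
5. **Validation.** Matrix **D** holds each user's average day (mean
   min/h). Three classifiers — multinomial logistic regression (L2,
   newton-cg), gradient-boosted trees (100 trees, depth 5, α = 0.1), and a
   fully connected 18-128-64-32-4 ReLU network trained 25 epochs with Adam
   — predict the group label on a stratified 80/20 split and are combined
   by majority vote (ties broken by the best individual classifier).
   Reported: accuracy, per-class / micro / macro one-vs-rest ROC-AUC, and
   the tree model's gain importances per hour.

## Worked example

```python
import pandas as pd
from wearday import (CohortConfig, generate_cohort, preprocess_logs,
                     cohort_use_summary, DayTypeKMeans, UserSegmentation,
                     build_user_proportions, build_average_day,
                     AverageDayMatrix, ClusterValidator)

logs, truth = generate_cohort(CohortConfig(n_users=400, seed=7))
A, audit = preprocess_logs(logs, truth.windows)
print(cohort_use_summary(A).summary())

day_res = DayTypeKMeans(A, k="auto", seed=7).fit()
print(day_res.summary())

B, _ = build_user_proportions(day_res.day_table(), day_res.model.type_names)
seg = UserSegmentation(B, seed=7).fit()
print(seg.summary())
```

prints (abridged):

```
Amount of hearing-aid use
-----------------------------------------
days: 10385   users: 336
pooled day mean 9.74 h (SD 5.11)
user means: CV 0.271, Q1 8.14 h, Q3 11.65 h
segments: light=84, medium=168, heavy=84

Day-type clustering (k-means++, k=3)
--------------------------------------------
days: 10385  retained after trimming: 9878
WSS/TSS: 0.300   mean silhouette: 0.466
  full_day             4229 days (42.8%), centroid total 14.2 h
  sporadic_evening     2899 days (29.3%), centroid total  2.3 h
  afternoon            2750 days (27.8%), centroid total 10.5 h
weekday association: chi2=0.1, p=9.68e-01, V=0.003

User clustering on B (336 users x 3 day types)
------------------------------------------------------------
method                                 silh      DB         CH
kmeans                               0.5039  0.6601        427
agglomerative_ward_euclidean         0.4974  0.6712        410
agglomerative_average_correlation    0.5021  0.6486        417
density_hierarchical_correlation     0.5600  0.5846        456 *
winner: density_hierarchical_correlation
  group 0: 62 users, predominant afternoon (0.65)
  group 1: 75 users, predominant sporadic_evening (0.66)
  group 2: 167 users, predominant full_day (0.65)
  noise users: 32
```

The elbow picks three day types whose centroids match the three behavioral
archetypes the generator planted (a ~14-h full day, a ~10-h afternoon day,
a ~2-h sporadic evening); the density method wins all three internal
metrics and recovers three user groups plus a noise set, each group
spending roughly two thirds of its days in its predominant day type.
Continuing with `ClusterValidator` on the average-day matrix yields an
ensemble test accuracy near 90% with micro-AUC ≈ 0.99 — the groups are
real enough for a classifier to find them from an independent
representation of the same users.

The same flow is available from the shell:

```sh
wearday run-all --config cfg.yaml --out run/      # or stage by stage:
wearday simulate --out run/ && wearday preprocess --in run/ --out run/
wearday stats --out run/ && wearday cluster-days --k auto --out run/
wearday cluster-users --out run/ && wearday validate --out run/
```

## Layout

```
src/wearday/
  simulate.py    synthetic cohort generator (archetypes, Dirichlet mixtures,
                 disconnection windows, ground truth)
  preprocess.py  binaural resolution, imputation, filtering, matrix A
  stats.py       amount-of-use descriptives and the variability curve
  daytypes.py    day-type k-means, elbow, silhouette, PCA, trimming, naming
  users.py       proportion matrix B, four clusterings, metric selection
  validate.py    average-day matrix D, classifier ensemble, ROC-AUC report
  pipeline.py    orchestration, YAML config, hashed run manifest
  cli.py         the `wearday` command
docs/methods.md  modelling assumptions, parameter choices, limitations
```
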