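# Methods

This note documents the models, conventions and design choices behind
`sweatvoc`, in the order data flows through the two arms.

## GC-MS curation

Per-sample exports are lists of (retention time, integrated peak area).
Curation rounds retention times **half away from zero** to one decimal —
the fixed-decimal convention of chromatography reports; banker's rounding
was rejected because its tie behaviour differs across platforms — and
merges peaks that collapse onto one rounded value. The default merge rule
is **sum** (total abundance is conserved; `max` is available). Consolidation
takes the union of rounded retention times across samples, ascending;
column names are `format(rt, ".10g")` strings that parse back to the float
bit-exactly. A sample without a peak at some retention time gets a
**missing** entry, never a zero: a zero would be a measured absence, which
integration software does not report. Features with no observed non-zero
entry are dropped before analysis.

Internal-standard (limonene) division is implemented
(`normalize_to_internal_standard`) but **off by default**: a spiked
standard guarantees run-to-run comparability, and quantitative division is
an explicit analyst decision.

## Imputation

Missing areas are filled by a centered moving average down each feature
column, window 3 (one neighbour on each side, in stored sample order,
matching time-ordered acquisition). All imputed values read the *original*
observations, so the result is independent of cell visiting order and the
operation is idempotent; a fully-missing window falls back to the column
mean. Pipeline order is impute → normalize (imputation operates on raw
areas); this order is fixed and recorded in the run config.

## Normalization

Seven per-feature transforms with parameters learned on a training matrix
and re-applied unchanged to held-out data: min–max, z-score, quantile
(reference distribution = per-rank means of the sorted training columns;
held-out values mapped through midranks and interpolation), Pareto
(center / sqrt(sd)), autoscale (center / sd), natural log (offset 1 added
only when zeros are present; raw areas are ≫ 1 so the offset is immaterial
otherwise) and square root. Standard deviations use the **population
(ddof = 0)** convention with a 1e-12 floor for constant features; z-score
and autoscale are therefore the same transform and both names are accepted.
Autoscaling is the pipeline default — it weights all features equally,
which suits peak areas spanning four orders of magnitude.

## Feature screening

Each feature is tested with the two-sided Wilcoxon rank-sum test: midranks
for ties; exact enumeration of the permutation distribution when the pooled
size is ≤ 12 and tie-free; otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction (numerically
identical to the standard asymptotic Mann–Whitney p). Degenerate
constant data returns p = 1. Features at raw p < 0.05 are retained — **no
multiple-testing correction by default**, mirroring small-cohort
volatilomics practice (a Benjamini–Hochberg option exists). If *no* feature
is significant (taken literally: zero features), the 13 highest-variance
features are selected instead; fallback variances are computed on the
pre-scaling matrix, because autoscaling flattens all variances to one.
Monte-Carlo calibration (pooled across seeds during development) puts the
test's type-I error at ≈ 0.047 at n = 30 + 30, α = 0.05: the continuity
correction makes it slightly conservative.

## Latent-variable models

**PCA** is the SVD of the column-centered matrix; explained-variance ratios
are squared singular values over total centered variance. **PLS-DA** is
NIPALS PLS1 against the centered 0/1 class dummy (CO → 0, CRC → 1); a
two-column one-hot target adds nothing for two classes. Per-component
Y-variance SS_a = q_a² t_aᵀt_a feeds the VIP formula; Σ VIP² = p holds to
1e-6 relative and is asserted in tests. When X has no class covariance at
all, the first weight falls back to the dominant PC direction so the fit is
defined (its y-loading is ~0). All component signs follow one convention —
the largest-|entry| element of the weight/loading is positive — so scores
and plots are bit-reproducible. With as many components as the rank of X,
PLS predictions coincide with least squares; this limit is tested.

**VIP threshold.** The reported-score cutoff surfaced in the config is 0.1;
note the conventional chemometrics cutoff is 1.0 (the VIP mean square is
identically 1, so 1.0 marks "above average importance"). VIPs are computed
over the *selected* feature set, i.e. the features the PLS model actually
saw; ranks over the full feature universe are available by selecting
everything.

**OSC** uses the iterative NIPALS-style variant (recorded in model
metadata): starting from the first PC score, the score is orthogonalized
against the centered class dummy, regressed back onto X for a unit weight
vector (an inner PLS step), and recomputed until the relative score change
falls below 1e-6 (cap 500 iterations; non-convergence raises with the last
delta). The converged score is exactly orthogonalized before its rank-one
component is removed, so every stored score has |corr with y| at rounding
error. Simpler direct-orthogonalization variants were rejected in favour of
the iterative correction. One component is removed by default; stored
weights transform held-out data without touching its labels. On data with
no y-orthogonal structure the matrix passes through unchanged.

**PERMANOVA** computes Anderson's pseudo-F from the Euclidean distance
matrix, F = (SS_between/(g−1))/(SS_within/(n−g)), with
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) over seeded label permutations;
999 permutations by default. The distance metric and permutation count are
package choices, logged with every result.

## Classification and evaluation

Stratified k-fold (default 5) assigns each class's samples to folds with
counts differing by ≤ 1, extras going to the folds with the smallest
running totals, so total fold sizes are as even as the class counts permit
(34 + 31 at k = 5 yields five folds of exactly 13). k-NN uses Euclidean
distances and k = 5; vote ties break by smaller mean distance, then to the
negative class; its ROC score is the CRC vote fraction — an assumption,
since vote-based classifiers have no canonical continuous score. LDA is
the Gaussian equal-covariance rule with a small ridge (ε·mean-diagonal) on
the pooled covariance; scores are posterior log-odds. Logistic regression
is Newton/IRLS on mean log-loss + (λ/2)‖w‖² (intercept unpenalized,
gradient norm < 1e-6). The linear SVM is hinge-loss dual coordinate
descent, liblinear-style, with the bias as an augmented regularized
feature (projected-gradient tolerance 1e-4).

Fold confusion counts are **pooled** into one whole-cohort matrix rather
than averaging per-fold metrics; the per-class panel is produced by role
reversal and a single overall accuracy is reported for both classes (the
two per-class "accuracies" sometimes tabulated separately are the same
quantity). Percentages are rounded to one decimal only at the reporting
layer. AUC is the trapezoid over the threshold sweep, equal to the
Mann–Whitney pair-counting statistic with half-credit for ties.

**Leakage policy.** `as_paper` mode fits normalization, selection,
PLS-DA/OSC on all samples and cross-validates only the classifier;
`honest` mode refits everything per training fold and transforms the
held-out fold without its labels. Honest imputation treats each fold's
rows separately, with training column means as the last-resort fallback.
On the default GC-MS generator the two modes differ by roughly 20 accuracy
points (≈ 91 vs ≈ 69 median over seeds) — the size of the optimism bought
by transform leakage at this cohort size.

## Synthetic generators

The generators define the study conditions under which the pipelines are
validated; they are first-class, tested code.

**GC-MS** (default 34 controls + 31 cases × 187 retention-time features):
peak areas are lognormal — positive and right-skewed — with a per-feature
geometric mean drawn once from a broad plausible-area range and shared by
both groups, except for 13 informative markers whose group geometric means
are the reference mean areas of the 13 discriminant sweat volatiles (e.g.
RT 10.7 min: 1.87e6 in controls vs 8.39e5 in cases). Missingness is
completely at random at rate 0.05 (no mechanism is known). `noise_cv`
parameterizes the log-scale sigma via σ = sqrt(ln(1 + cv²)).

The default `noise_cv = 1.75` was calibrated once so that the synthetic
cohort's pipeline accuracy lands in the realistic 80–90% band rather than
saturating: the 13 printed marker means are mutually inconsistent with any
single-sigma lognormal model (their reported p-values imply standardized
effects of ~0.4–0.7 across the board, while the mean ratios span log-ratios
0.21–1.57), so a single sigma must compromise. The chosen value preserves
the reported significance range for the strong markers at the cohort size
and leaves the weakest two markers individually undetectable — which is
why recovery guarantees in the tests apply to markers with |log ratio|
≥ 0.4.

**E-nose** (default 35 + 33 recordings, 14 sensors, 1 Hz, 60 s baseline +
120 s exposure): each channel is a per-sensor baseline level, plus a
class-dependent response plateau during the sample phase (step onset; rise
kinetics are out of scope), plus a per-sample **linear drift** (slope ~
N(0, 0.01 signal units/s), fixed per-sensor gains 0.8–1.2, identical
mechanism in both classes), plus two **board-level common-mode factors**
(log-amplitude sd 0.35) with zero-sum loading patterns — the digital-PCB
vs analog-PCB contrast and a within-board half contrast — plus white noise
(sd 0.01). Common-mode sensitivity shared across sensors on one board is
characteristic of metal-oxide arrays (temperature/humidity coupling); the
zero-sum patterns keep the factors distinct from the all-sensor drift
direction, so drift and the two factors occupy the three leading
unsupervised directions. Class amplitudes default to ~1–1.5 (controls)
modulated ×1.5 / ×0.65 on alternating sensors (cases), an alternating
pattern roughly orthogonal to all three nuisance directions. Per-sensor
response variability is lognormal with cv 0.15.

Under these defaults the data are genuinely drift-dominated: the first
principal component of the raw Max–Min matrix tracks the drift slope, not
the class, and the no-OSC pipeline sits near chance while OSC(1) restores
~93% median accuracy. With equal class amplitudes (null configuration) the
full honest pipeline is calibrated to chance within binomial bounds.

**What the generators do not emulate:** real sensor adsorption kinetics,
humidity response surfaces, chromatogram-level ion traces,
compound-identity structure, inter-feature biological correlation, or
batch effects. Passing tests therefore demonstrate that the *algorithms*
behave as specified under the stated statistical structure — not that any
particular clinical accuracy would be attained on new cohorts.

## Problem sizes used in validation

Property studies run 20 seeds of the default cohorts (65 × 187 GC-MS;
68 × 14 E-nose), 2000 Monte-Carlo null replicates for test calibration,
and brute-force oracle comparisons on instances of ≤ 50 samples — sizes at
which exhaustive enumeration (rank-sum distributions, label assignments,
all-pairs distances) is exact and fast.

## Known limitations

- Two classes only; no multi-class PLS-DA or one-vs-rest wrappers.
- OSC removes linear structure; nonlinear drift (e.g. folded negative
  slopes in the Max–Min feature) is only partially captured by one
  component.
- The exact Wilcoxon branch enumerates only tie-free pooled samples ≤ 12;
  beyond that the tie-corrected normal approximation is used.
- No hyperparameter search, kernel methods, class weighting or calibration
  curves; the cohort is near-balanced and the reference pipelines fix
  their settings a priori.
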