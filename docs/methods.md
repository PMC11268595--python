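# Methods

## Problem setting

Automated mental-health assessment systems classify subjects (e.g.
control vs. mental health condition, MHC) from features derived from
interview recordings. Because such systems are trained on small clinical
cohorts, their error profiles can differ across demographic groups even
when overall accuracy looks acceptable. `fairdx` implements the group-
fairness workflow for this setting: audit the dataset's composition,
measure classifier fairness as ratio metrics over repeated
cross-validation, and mitigate unfairness by post-training per-group
threshold optimization. Because the kind of clinical dataset this
targets is typically private, the package ships a synthetic cohort
generator with controllable group structure; every stage is validated
against it.

## Fairness metrics

For a sensitive attribute `k` with groups `G` and privileged group `g*`,
let `S_g` be the selection rate (fraction of group `g` predicted
positive), and `TPR_g`, `FPR_g` the within-group true/false positive
rates. The four ratio metrics are

- `D_k  = min_g S_g / max_g S_g` (overall demographic parity ratio),
- `D_g* = min_{g≠g*} S_g / S_g*` (privilege-referenced parity ratio),
- `O_k  = min( (min_g TPR_g + δ)/(max_g TPR_g + δ),
               (min_g FPR_g + δ)/(max_g FPR_g + δ) )`,
- `O_g* = min( min_{g≠g*} (TPR_g + δ)/(TPR_g* + δ),
               min_{g≠g*} (FPR_g* + δ)/(FPR_g + δ) )`,

with δ = 0.001 by default (overridable), which keeps the equalized-odds
ratios finite when a rate is zero; when all rates are zero each term is
δ/δ = 1. A value of 1 means parity; distance from 1 means disparity.

Numerical conventions, chosen where the formulas are silent:

- **Undefined rates are flagged, not zeroed.** A group with no
  positives has no TPR; with no negatives, no FPR. Such groups are
  excluded from the ratio with a recorded warning. Coercing to zero
  would silently collapse ratios to 0 or δ-artifacts.
- **`D_g*` and `O_g*` are not clipped.** Both can exceed 1 when the
  disparity favors the unprivileged groups; the formulas are applied
  as written. `symmetric_disparity` (`min(x, 1/x)`) is provided as a
  clearly-labelled extension for summarizing on a one-sided scale.
  Note the `O_g*` FPR term is oriented with the privileged FPR in the
  numerator — both terms fall below 1 exactly when the unprivileged
  group has lower TPR and higher FPR; the asymmetry is intentional and
  documented rather than "corrected".
- **Per-group macro-F1** is the unweighted mean of the two per-class F1
  scores. Zero-support conventions: a class absent from both the
  group's truth and its predictions contributes F1 = 1 (a degenerate
  but perfect prediction); absent from truth but predicted, 0.

## Dataset audit

Binary outcomes are defined either directly (clinician label) or by a
strict scale cutoff: positive iff score > 10 on PHQ-9 (range 0–27) or
GAD-7 (0–21). The strict inequality follows the explicit group
definitions used for this kind of cohort (score ≤ 10 is the negative
class), although screening guidelines are often phrased "10 or above";
the cutoff is a parameter, so either convention is reachable.

Continuous demographics are binarized as age ≥ 40 ("older", the
privileged level) and education ≤ 16 years ("college or below", the
privileged level); gender and race are categorical with privileged
levels "male" and "white". Groups smaller than `min_group_size`
(default 5) are excluded from *that attribute's analyses only* — the
subjects remain in every other attribute's analyses. Missing values are
treated the same way.

Tests: Pearson chi-square of group × label independence without
continuity correction, with a recorded warning when any expected cell
count is below 5 (small cohorts make this common; a silent switch to a
different test would be more surprising than a flagged fragile one);
two-sided Mann-Whitney rank-sum for continuous covariates between label
classes, exact enumeration when both samples have ≤ 12 observations and
no ties, otherwise the tie-corrected normal approximation. Significance
is a flat α = 0.05 with no multiple-testing correction; the report
carries the number of tests performed so users can correct afterwards.

## Equalized-odds threshold optimization

The post-processor implements the derived-predictor construction of
Hardt, Price & Srebro: with randomization, a group can realize any
operating point in the convex hull of its ROC points (the hull contains
the diagonal, since a score-independent coin is a valid classifier).
The equalized-odds-feasible region is the intersection of the groups'
hulls, whose upper boundary at FPR `x` is `min_g hull_g(x)` because
each hull's boundary is concave. Expected accuracy at a common point is
`π·TPR + (1−π)·(1−FPR)` with π the pooled prevalence, linear in the
point, so the optimum lies on the boundary; it is found by scanning the
FPR axis on a grid (step `grid_resolution`, default 0.001, which bounds
the optimality loss) and breaking ties toward smaller FPR.

Each group's rule realizing the target uses at most three primitives:
the two deterministic thresholds whose hull vertices bracket the target
FPR, mixed with weight `weight_lo`, and — for groups whose hull lies
strictly above the target — a coin predicting positive with probability
equal to the target FPR, mixed in with probability `p_ignore`. Two
thresholds alone can only reach a hull's boundary; the coin reaches the
interior, and with it every non-degenerate group hits the common
(FPR, TPR) exactly on its fitting data. Groups with a single class in
the fitting data (common at 73 subjects / 5 folds) fall back to the
pooled accuracy-optimal single threshold, flagged on the policy.

Prediction-time randomization is keyed per row by `(seed, subject_id)`
(SHA-256 of the id feeding a dedicated generator), so predictions are
reproducible and independent of table order.

Inside cross-validation the policy is fitted on the **training** fold's
scores and applied to the test fold — no test labels leak into the
thresholds. The training-fold ROC is optimistic for the classifier's
own training scores, which is logged as a caveat; the protocol itself
does not state where thresholds should be learned, and the
leakage-free choice is the defensible default.

## Evaluation protocol

R-times repeated, label-stratified K-fold cross-validation (defaults
R = 100, K = 5; tests and the acceptance script use R = 20 with a
400-subject cohort, sizes at which the metric distributions are already
stable). Per repeat the K test folds are pooled into one prediction set
before metrics are computed — per-fold group cells at n ≈ 73/5 are too
small for stable rates — giving R values per metric, summarized by
median, IQR, and outliers beyond 1.5·IQR. Scores are turned into labels
by strict `score > 0.5` wherever no mitigation applies. Late fusion:
majority vote over member labels (ties broken by the weighted rule) and
probability-weighted vote (mean member score, thresholded). The
reference scorer is an L2-regularized logistic model with within-fold
standardization; any estimator with `predict_proba` plugs in. Metric
distributions are compared with unpaired two-sided Mann-Whitney tests.

## Synthetic cohort generator

The generator emulates a small remote-interview cohort: exact group
sizes per attribute (a 73-subject demo with a ~70% MHC base rate,
gender 38/33/2 and race 41/17/9/2/4 splits mirroring the kind of
composition where n < 5 minorities are excluded); clinical labels as
Bernoulli draws with per-(attribute, group) base rates (differential
base rates are how label–demographic dependence, e.g. an odds ratio of
6, is induced for audit power checks — when several attributes carry
base rates a subject's probability is the mean of the applicable ones);
scale scores as label-conditional Gaussians, discretized and clipped to
the instrument range (defaults: PHQ-9 14±4 positive vs 5±3 negative),
giving controllable overlap at the >10 cutoff; modality features as
label- and group-conditional spherical Gaussians whose class-mean
separation can differ by group. The spherical design has a closed-form
within-group Bayes accuracy, Φ(separation/2σ), used to validate the
separability knob analytically.

Prediction fixtures are constructed with *exact* confusion counts (TPR
0.9 with 10 positives is exactly 9 true positives; unrepresentable
targets raise an error naming the nearest representable rate), making
them machine-precision oracles for the metric formulas; a sampled mode
draws Bernoulli predictions instead for stochastic checks.

What the generator does *not* emulate: raw audio/video signals and
their feature extractors, temporal dynamics, measurement artifacts,
correlated demographics (attributes are assigned independently), or
label noise from clinician disagreement. Passing tests therefore
demonstrate correctness of the metrics, the optimizer and the protocol
under known group structure — not that any particular real-world system
is fair or unfair.

## Known limitations

- The randomized decision rule is appropriate for population-level
  fairness accounting, but randomizing individual clinical decisions
  raises ethical questions outside this package's scope.
- Equalized odds is enforced on the fitting data; generalization of the
  equalized operating point to new data degrades with training-fold
  size.
- The chi-square audit is asymptotic; at the cohort sizes targeted here
  expected counts below 5 are flagged rather than exact tests
  substituted.
- Group-fairness ratios say nothing about calibration, individual
  fairness, or counterfactual fairness.
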