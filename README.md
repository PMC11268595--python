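# fairdx

Group-fairness auditing and post-training equalized-odds mitigation for
binary clinical classifiers, built for the small demographically
structured cohorts typical of remote mental-health assessment studies
(tens of subjects, multiple feature "modalities", clinician-assigned
labels).

`fairdx` answers three questions about such a study:

1. **Is the dataset itself skewed?** Composition audit: per-group counts
   and selection rates for clinical and self-rated (PHQ-9 > 10,
   GAD-7 > 10) labels, small-group (n < 5) exclusions, chi-square
   independence tests and Mann-Whitney covariate comparisons.
2. **Are the classifiers fair?** Four ratio metrics per sensitive
   attribute `k` (groups `G`, privileged group `g*`), computed per
   repeat of R×K-fold stratified cross-validation:

   - overall demographic parity ratio `D_k = min_g S_g / max_g S_g`
   - privilege-referenced `D_g* = min_{g≠g*} S_g / S_g*`
   - overall equalized odds ratio
     `O_k = min((min TPR+δ)/(max TPR+δ), (min FPR+δ)/(max FPR+δ))`
   - privilege-referenced
     `O_g* = min(min_{g≠g*}(TPR_g+δ)/(TPR_g*+δ), min_{g≠g*}(FPR_g*+δ)/(FPR_g+δ))`

   with selection rate `S_g`, within-group TPR/FPR, and δ = 0.001
   smoothing; 1 = parity. Late fusion (majority and probability-weighted
   votes) and per-group macro-F1 are part of the harness.
3. **Can the unfairness be mitigated?** A from-scratch implementation of
   the derived-predictor post-processing method (Hardt et al.): per-group
   randomized thresholds that drive every group to a common (FPR, TPR)
   operating point — found by scanning the intersection of the groups'
   ROC convex hulls — maximizing accuracy subject to equalized odds.
   Exposed as a scikit-learn style estimator
   (`EqualizedOddsThresholdOptimizer`) and wired into the CV harness.

Real interview datasets of this kind are private, so the package
includes a synthetic cohort generator (exact group sizes, per-group
label base rates, per-group feature separability, instrument-range
scale scores) that makes every pipeline stage testable with known
ground truth. See `docs/methods.md` for the models and conventions.

## Worked example

```python
import warnings
import fairdx as fx

# 73-subject demo cohort: gender 38/33/2, race 41/17/9/2/4, ~70% MHC
subjects, features = fx.generate_cohort(fx.default_cohort_config(seed=7))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")   # small-cohort chi-square caveats
    report = fx.audit_composition(subjects)
print(report.composition.query(
    "attribute == 'gender' and label == 'clinical_mhc'")
    [["group", "n", "n_positive", "selection_rate"]].to_string(index=False))
row = report.chi_square.query(
    "attribute == 'gender' and label == 'clinical_mhc'").iloc[0]
print(f"chi-square p = {row['p_value']:.3f} (significant: {row['significant']})")
```

```
 group  n  n_positive  selection_rate
female 38          26        0.684211
  male 33          21        0.636364
chi-square p = 0.671 (significant: False)
```

The nonbinary group (n = 2) is excluded from gender analyses only; the
MHC selection rates of the retained groups are close and the chi-square
test finds no label–gender dependence.

```python
labels = subjects.set_index("subject_id")["clinical_label"]
groups = subjects.set_index("subject_id")[["gender"]]
preds = fx.run_repeated_cv(features, labels, groups,
                           n_repeats=10, n_folds=5, seed=7,
                           mitigate="gender")
spec = fx.SensitiveAttributeSpec("gender", ("female", "male"), "male")
fair = fx.summarize_fairness(preds, [spec])
print(fair.summary.query("group == '' and classifier == 'logistic:facial'")
      [["mitigation", "metric", "median", "iqr"]].round(3).to_string(index=False))
```

```
mitigation         metric  median   iqr
      none    dpr_overall   0.636 0.083
      none dpr_privileged   1.261 0.185
      none    eor_overall   0.620 0.285
      none eor_privileged   0.620 0.285
      none       macro_f1   0.717 0.037
    gender    dpr_overall   0.632 0.113
    gender dpr_privileged   0.992 0.048
    gender    eor_overall   0.800 0.250
    gender eor_privileged   0.831 0.227
    gender       macro_f1   0.678 0.057
```

Each row summarizes 10 CV repeats (median and IQR across repeats, test
folds pooled within each repeat). Before mitigation the facial-modality
classifier's overall equalized odds ratio has median 0.62 — its error
rates differ substantially between women and men — and the
privilege-referenced parity ratio of 1.26 means women are *selected
more often* than the privileged male group. Equalized-odds thresholding
per gender raises the EOR median to 0.80 and pulls the
privilege-referenced DPR to ~0.99, at the cost of macro-F1 dropping
from 0.72 to 0.68: fairer, slightly less accurate.

The same pipeline is available from the shell:

```bash
fairdx simulate --seed 7 --out cohort/
fairdx audit --subjects cohort/subjects.csv --out audit/
fairdx evaluate --subjects cohort/subjects.csv \
    --features cohort/features_facial.csv \
    --features cohort/features_acoustic.csv \
    --repeats 10 --folds 5 --seed 7 --fuse weighted \
    --mitigate gender --out eval/
```

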