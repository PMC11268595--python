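"""Repeated stratified cross-validation harness with late fusion.

Implements the evaluation protocol used throughout the package: R-times
repeated, label-stratified K-fold cross-validation (defaults R=100, K=5)
over pluggable per-modality scorers; per test fold the scorer is fitted
on the training subjects only and scored on the held-out subjects, and
all test-fold outputs are collected into a long-format prediction table
with full provenance (subject, repeat, fold, classifier, mitigation
tag). Two decision-level fusion rules combine unimodal outputs: a
majority vote of the predicted labels (ties broken by the weighted
rule), and a probability-weighted vote (mean of member scores,
thresholded). Fairness summaries pool each repeat's K test folds into
one prediction set per repeat — per-fold group cells are too small for
stable TPR/FPR at cohort sizes near 73 — yielding a distribution of R
values per metric, summarized by median/IQR/outliers as in standard
boxplot conventions.

Optional equalized-odds mitigation is part of the cross-validation
process: the per-group threshold policy is fitted on the *training*
fold's scores (no test-label leakage; the in-sample ROC is optimistic,
which is logged) and applied to the test fold. Both the unmitigated and
mitigated predictions are emitted, tagged in the ``mitigation`` column.

The decision rule for raw scores is strictly-greater-than 0.5,
everywhere a score is turned into an unmitigated label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .audit import SensitiveAttributeSpec, mann_whitney
from .metrics import (DEFAULT_DELTA, compute_fairness_ratios,
                      compute_group_rates, macro_f1)
from .mitigation import apply_policy, fit_eo_policy

__all__ = [
    "ClassifierSpec",
    "FairnessReport",
    "ComparisonResult",
    "reference_classifier",
    "run_repeated_cv",
    "fuse_majority",
    "fuse_weighted",
    "summarize_fairness",
    "compare_distributions",
]

logger = logging.getLogger(__name__)

SCORE_THRESHOLD = 0.5
KEY_COLS = ["subject_id", "repeat", "fold", "mitigation"]


def reference_classifier(seed: int = 0) -> Pipeline:
    """The harness's built-in scorer: within-fold feature standardization
    followed by an L2-regularized linear logistic model. A minimal,
    well-calibrated stand-in for arbitrary per-modality classifiers; any
    estimator with ``predict_proba`` plugs in instead."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=1.0, max_iter=1000, random_state=seed)),
    ])


@dataclass(frozen=True)
class ClassifierSpec:
    """A named scorer factory: ``build(seed)`` returns an unfitted
    estimator with fit/predict_proba; scores are P(label = 1) in [0, 1]."""

    name: str
    build: Callable[[int], object] = reference_classifier


def run_repeated_cv(
    features: Mapping[str, pd.DataFrame],
    labels: pd.Series,
    groups: pd.DataFrame,
    *,
    n_repeats: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    classifier: ClassifierSpec | None = None,
    mitigate: str | None = None,
    grid_resolution: float = 0.001,
) -> pd.DataFrame:
    """Run the repeated stratified CV protocol over all modalities.

    Parameters
    ----------
    features : mapping modality name -> feature block indexed by subject_id
    labels : binary Series indexed by subject_id
    groups : DataFrame of sensitive-attribute columns indexed by subject_id
    mitigate : optional attribute name; when given, an equalized-odds
        threshold policy is fitted per (repeat, fold, modality) on the
        training fold and applied to the test fold, and the table
        contains each test row twice, tagged ``mitigation`` = "none" and
        the attribute name.

    Returns the long-format prediction table. Fully reproducible from
    ``seed``. A training fold missing a class is skipped and logged.
    """
    if n_repeats < 1 or n_folds < 2:
        raise ValueError("need n_repeats >= 1 and n_folds >= 2")
    if labels.isna().any():
        raise ValueError("every subject needs a label")
    spec = classifier or ClassifierSpec("logistic")
    subject_ids = labels.index.to_numpy()
    y = labels.to_numpy(dtype=int)
    if mitigate is not None and mitigate not in groups.columns:
        raise ValueError(f"mitigation attribute {mitigate!r} not in groups")
    group_vals = {c: groups.reindex(labels.index)[c].to_numpy()
                  for c in groups.columns}
    blocks = {m: X.reindex(labels.index).to_numpy(dtype=float)
              for m, X in features.items()}
    if mitigate is not None:
        logger.info("EO policies are fitted on training-fold scores; the "
                    "in-sample ROC is optimistic for small folds")

    rng = np.random.default_rng(seed)
    records: list[dict] = []
    for rep in range(1, n_repeats + 1):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for fold, (tr, te) in enumerate(skf.split(np.zeros_like(y), y), start=1):
            if len(np.unique(y[tr])) < 2:
                logger.warning("repeat %d fold %d: single-class training fold "
                               "skipped", rep, fold)
                continue
            for modality, X in blocks.items():
                est = spec.build(int(rng.integers(2**31 - 1)))
                est.fit(X[tr], y[tr])
                score_te = est.predict_proba(X[te])[:, 1]
                base = {
                    "repeat": rep, "fold": fold,
                    "classifier": f"{spec.name}:{modality}",
                }
                variants: list[tuple[str, np.ndarray]] = [
                    ("none", (score_te > SCORE_THRESHOLD).astype(int))]
                if mitigate is not None:
                    score_tr = est.predict_proba(X[tr])[:, 1]
                    policy = fit_eo_policy(
                        score_tr, y[tr], group_vals[mitigate][tr],
                        grid_resolution=grid_resolution, seed=seed)
                    y_mit = apply_policy(
                        policy, score_te, group_vals[mitigate][te],
                        seed=seed, subject_ids=subject_ids[te])
                    variants.append((mitigate, y_mit))
                for mit_tag, preds in variants:
                    for j, i in enumerate(te):
                        rec = {
                            "subject_id": subject_ids[i],
                            **base,
                            "mitigation": mit_tag,
                            "y_true": int(y[i]),
                            "score": float(score_te[j]),
                            "y_pred": int(preds[j]),
                        }
                        for c, vals in group_vals.items():
                            rec[c] = vals[i]
                        records.append(rec)
    return pd.DataFrame(records)


def _check_aligned(tables: Sequence[pd.DataFrame]) -> None:
    ref = tables[0].set_index(KEY_COLS).index
    for t in tables[1:]:
        idx = t.set_index(KEY_COLS).index
        if not ref.sort_values().equals(idx.sort_values()):
            offending = ref.symmetric_difference(idx).tolist()[:10]
            raise ValueError(f"prediction tables are misaligned on keys: "
                             f"{offending}")


def _fused_frame(tables: Sequence[pd.DataFrame], name: str) -> pd.DataFrame:
    meta_cols = [c for c in tables[0].columns
                 if c not in {"score", "y_pred", "classifier"}]
    merged = pd.concat(tables, ignore_index=True)
    agg = merged.groupby(KEY_COLS, sort=False).agg(
        mean_pred=("y_pred", "mean"), mean_score=("score", "mean"))
    meta = tables[0][meta_cols].drop_duplicates(KEY_COLS).set_index(KEY_COLS)
    out = meta.join(agg).reset_index()
    out["classifier"] = name
    return out


def fuse_majority(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Majority vote over member predicted labels.

    Ties (possible with an even member count) are broken by the
    probability-weighted rule: mean member score > 0.5. The fused score
    column is the mean member score, for downstream use.
    """
    if len(tables) < 2:
        raise ValueError("majority fusion needs at least 2 member tables")
    _check_aligned(tables)
    out = _fused_frame(tables, "majority_vote")
    tie = np.isclose(out["mean_pred"], 0.5)
    out["y_pred"] = np.where(
        tie,
        (out["mean_score"] > SCORE_THRESHOLD).astype(int),
        (out["mean_pred"] > 0.5).astype(int),
    )
    out["score"] = out.pop("mean_score")
    out = out.drop(columns=["mean_pred"])
    return out


def fuse_weighted(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Probability-weighted vote: fused score = mean of member scores,
    fused label = 1 iff fused score > 0.5. With a single member this is
    the identity on that member's scores."""
    if not tables:
        raise ValueError("no member tables")
    for t in tables:
        s = t["score"]
        if ((s < 0) | (s > 1)).any():
            raise ValueError("member scores must lie in [0, 1]")
    _check_aligned(tables)
    out = _fused_frame(tables, "weighted_vote")
    out["score"] = out.pop("mean_score")
    out["y_pred"] = (out["score"] > SCORE_THRESHOLD).astype(int)
    out = out.drop(columns=["mean_pred"])
    return out


@dataclass
class FairnessReport:
    """Per-repeat fairness metric values and their distribution summary.

    ``values``: tidy frame (classifier, mitigation, attribute, repeat,
    metric, group, value, reason) — ``group`` is empty for the four
    ratio metrics and pooled macro-F1, and names the group for
    per-group macro-F1 rows; undefined values carry an NA value and a
    reason code. ``summary``: median, quartiles, IQR and outlier count
    (beyond 1.5 IQR from the quartiles) per metric distribution.
    """

    values: pd.DataFrame
    summary: pd.DataFrame
    delta: float = DEFAULT_DELTA


def _attribute_column(table: pd.DataFrame,
                      spec: SensitiveAttributeSpec) -> pd.Series:
    if spec.name in table.columns:
        return table[spec.name]
    return spec.realize(table)


def summarize_fairness(
    table: pd.DataFrame,
    attribute_specs: Sequence[SensitiveAttributeSpec],
    delta: float = DEFAULT_DELTA,
) -> FairnessReport:
    """Per-repeat fairness metrics of a prediction table.

    For each (classifier, mitigation, attribute): per repeat, all K test
    folds are pooled, groups below the attribute's minimum size (or with
    missing values) are excluded for that attribute only, and the four
    ratio metrics plus pooled and per-group macro-F1 are computed.
    """
    if table.empty:
        raise ValueError("empty prediction table")
    rows: list[dict] = []
    for (clf, mit), part in table.groupby(["classifier", "mitigation"],
                                          sort=False):
        for spec in attribute_specs:
            col = _attribute_column(part, spec)
            work = part.assign(**{spec.name: col})
            counts = col.value_counts()
            small = set(counts[counts < spec.min_group_size].index)
            keep = col.notna() & ~col.isin(small)
            work = work[keep]
            for rep, sl in work.groupby("repeat", sort=True):
                ratios = compute_fairness_ratios(
                    sl, spec.name, spec.privileged, delta)
                reason = "; ".join(ratios.warnings) or None
                for metric, value in ratios.as_dict().items():
                    rows.append({
                        "classifier": clf, "mitigation": mit,
                        "attribute": spec.name, "repeat": rep,
                        "metric": metric, "group": "",
                        "value": np.nan if value is None else value,
                        "reason": reason if value is None else None,
                    })
                rows.append({
                    "classifier": clf, "mitigation": mit,
                    "attribute": spec.name, "repeat": rep,
                    "metric": "macro_f1", "group": "",
                    "value": macro_f1(sl["y_true"], sl["y_pred"]),
                    "reason": None,
                })
                for g, gr in compute_group_rates(sl, spec.name).items():
                    rows.append({
                        "classifier": clf, "mitigation": mit,
                        "attribute": spec.name, "repeat": rep,
                        "metric": "macro_f1", "group": g,
                        "value": np.nan if gr.macro_f1 is None else gr.macro_f1,
                        "reason": "empty-group" if gr.macro_f1 is None else None,
                    })
    values = pd.DataFrame(rows)

    summaries: list[dict] = []
    for keys, part in values.groupby(
            ["classifier", "mitigation", "attribute", "metric", "group"],
            sort=False):
        v = part["value"].dropna().to_numpy()
        rec = dict(zip(["classifier", "mitigation", "attribute", "metric",
                        "group"], keys))
        rec["n"] = len(v)
        rec["n_undefined"] = int(part["value"].isna().sum())
        if len(v):
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            rec.update(median=med, q1=q1, q3=q3, iqr=iqr,
                       n_outliers=int(np.sum((v < q1 - 1.5 * iqr)
                                             | (v > q3 + 1.5 * iqr))),
                       mean=float(np.mean(v)))
        else:
            rec.update(median=np.nan, q1=np.nan, q3=np.nan, iqr=np.nan,
                       n_outliers=0, mean=np.nan)
        summaries.append(rec)
    return FairnessReport(values=values, summary=pd.DataFrame(summaries),
                          delta=delta)


class ComparisonResult(NamedTuple):
    p_value: float
    significant: bool


def compare_distributions(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Two-sided Mann-Whitney rank-sum comparison of two metric
    distributions, with the significance decision at ``alpha``."""
    p = mann_whitney(np.asarray(a, float), np.asarray(b, float))
    return ComparisonResult(p_value=p, significant=bool(p < alpha))
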