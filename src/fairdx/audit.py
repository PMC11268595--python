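"""Dataset-composition fairness audit.

Audits the demographic composition of a labelled cohort before any model
is trained: binarizes scale scores and continuous demographics, excludes
demographic groups too small to analyse (n below a threshold, default 5,
dropped from that attribute's analyses only), tabulates per-group counts
and selection rates, and tests label-demographic dependence (Pearson
chi-square) and covariate differences between label classes
(Mann-Whitney rank-sum).

Conventions follow the emulated study design: a scale score is positive
iff strictly greater than the cutoff (PHQ-9 > 10 self-rated depression,
GAD-7 > 10 self-rated anxiety); age >= 40 is "older"; education <= 16
years is "college_or_below" (the privileged level for education). All
tests are two-sided with significance at alpha = 0.05 and no
multiple-testing correction; the report carries the number of tests
performed so users can apply their own.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SensitiveAttributeSpec",
    "LabelDefinition",
    "AuditReport",
    "binarize_scale",
    "apply_exclusions",
    "audit_composition",
    "mann_whitney",
    "default_attribute_specs",
    "default_label_definitions",
    "SmallExpectedCountWarning",
]

ALPHA = 0.05


class SmallExpectedCountWarning(UserWarning):
    """A chi-square contingency table has an expected cell count below 5."""


@dataclass(frozen=True)
class SensitiveAttributeSpec:
    """One demographic axis: its levels, privileged level, and optional
    binarization of a continuous source column.

    ``source`` names a continuous column (e.g. ``age_years``) that is cut
    into the two ``levels`` at ``threshold``: level[0] applies when the
    rule holds, level[1] otherwise. ``rule`` is ``"ge"`` (value >=
    threshold) or ``"le"`` (value <= threshold).
    """

    name: str
    levels: tuple[str, ...]
    privileged: str
    min_group_size: int = 5
    source: str | None = None
    threshold: float | None = None
    rule: str = "ge"

    def __post_init__(self) -> None:
        if self.privileged not in self.levels:
            raise ValueError(
                f"privileged level {self.privileged!r} not among levels {self.levels}")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.source is not None:
            if self.threshold is None or len(self.levels) != 2:
                raise ValueError("binarized attributes need a threshold and 2 levels")
            if self.rule not in ("ge", "le"):
                raise ValueError("rule must be 'ge' or 'le'")

    def realize(self, table: pd.DataFrame) -> pd.Series:
        """The attribute's group column, binarizing ``source`` if set."""
        if self.source is None:
            if self.name not in table.columns:
                raise ValueError(f"attribute column {self.name!r} missing")
            return table[self.name]
        if self.source not in table.columns:
            raise ValueError(f"source column {self.source!r} missing")
        vals = table[self.source]
        hit = vals >= self.threshold if self.rule == "ge" else vals <= self.threshold
        out = pd.Series(np.where(hit, self.levels[0], self.levels[1]),
                        index=table.index, name=self.name)
        return out.where(vals.notna(), other=pd.NA)


@dataclass(frozen=True)
class LabelDefinition:
    """A binary outcome: either a 0/1 column used directly, or a scale
    column cut at ``score > cutoff``."""

    name: str
    source: str
    cutoff: int | None = None

    def realize(self, table: pd.DataFrame) -> pd.Series:
        if self.source not in table.columns:
            raise ValueError(f"label source column {self.source!r} missing")
        if self.cutoff is None:
            col = table[self.source]
            bad = ~col.dropna().isin([0, 1])
            if bad.any():
                raise ValueError(f"label column {self.source!r} is not binary")
            return col
        return binarize_scale(table[self.source], self.cutoff)


def default_attribute_specs() -> list[SensitiveAttributeSpec]:
    """Gender (privileged: male), race (white), age (older, >= 40),
    education (college or below, <= 16 years)."""
    return [
        SensitiveAttributeSpec("gender", ("male", "female", "nonbinary"), "male"),
        SensitiveAttributeSpec(
            "race", ("white", "black", "asian", "hispanic", "other"), "white"),
        SensitiveAttributeSpec("age", ("older", "younger"), "older",
                               source="age_years", threshold=40, rule="ge"),
        SensitiveAttributeSpec("education", ("college_or_below", "above_college"),
                               "college_or_below", source="education_years",
                               threshold=16, rule="le"),
    ]


def default_label_definitions() -> list[LabelDefinition]:
    return [
        LabelDefinition("clinical_mhc", "clinical_label"),
        LabelDefinition("selfrated_depression", "phq9", cutoff=10),
        LabelDefinition("selfrated_anxiety", "gad7", cutoff=10),
    ]


def binarize_scale(scores: pd.Series, cutoff: int) -> pd.Series:
    """Positive (1) iff score strictly greater than ``cutoff``.

    Missing scores propagate as missing; non-integer or negative scores
    raise a ``ValueError`` naming the offending row.
    """
    out = pd.Series(pd.NA, index=scores.index, dtype="Int64")
    for idx, val in scores.items():
        if pd.isna(val):
            continue
        if float(val) != int(val) or val < 0:
            raise ValueError(f"invalid scale score {val!r} at row {idx!r}")
        out.loc[idx] = int(int(val) > cutoff)
    return out


def apply_exclusions(
    table: pd.DataFrame, spec: SensitiveAttributeSpec
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop rows whose group is smaller than ``spec.min_group_size``.

    The exclusion applies to *this attribute's analyses only*; callers
    audit each attribute from the full table. Rows with a missing
    attribute value are likewise excluded here. Returns the filtered
    table and a log of the dropped groups with their counts.
    """
    groups = spec.realize(table)
    log: list[dict] = []
    keep = groups.notna()
    n_missing = int((~keep).sum())
    if n_missing:
        log.append({"attribute": spec.name, "group": None, "count": n_missing,
                    "reason": "missing value"})
    counts = groups[keep].value_counts()
    for level, count in counts.items():
        if count < spec.min_group_size:
            keep &= groups != level
            log.append({"attribute": spec.name, "group": str(level),
                        "count": int(count),
                        "reason": f"group size {count} < {spec.min_group_size}"})
    filtered = table[keep].copy()
    filtered[spec.name] = groups[keep]
    return filtered, log


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact enumeration when both samples have <= 12 observations and no
    ties across them; otherwise the normal approximation with tie
    correction. Samples that are identical in all values give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        warnings.warn("all values tied across both samples; p = 1", UserWarning,
                      stacklevel=2)
        return 1.0
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (a.size <= 12 and b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class AuditReport:
    """Counts, selection rates, exclusions, and test results of one audit."""

    composition: pd.DataFrame  # attribute, group, label, n, n_positive, selection_rate
    chi_square: pd.DataFrame   # attribute, label, statistic, dof, p_value, significant, warning
    covariate_tests: pd.DataFrame  # covariate, label, p_value, significant
    exclusions: list[dict] = field(default_factory=list)
    alpha: float = ALPHA
    n_tests: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "composition": self.composition.to_dict(orient="records"),
            "chi_square": self.chi_square.to_dict(orient="records"),
            "covariate_tests": self.covariate_tests.to_dict(orient="records"),
            "exclusions": self.exclusions,
        }
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if obj is pd.NA or (isinstance(obj, float) and np.isnan(obj)):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def audit_composition(
    table: pd.DataFrame,
    attribute_specs: Sequence[SensitiveAttributeSpec] | None = None,
    label_definitions: Sequence[LabelDefinition] | None = None,
    covariates: Sequence[str] = ("age_years", "education_years"),
    alpha: float = ALPHA,
) -> AuditReport:
    """Run the full composition audit of a subject table.

    Per (attribute, label definition): group counts, positive counts and
    selection rates after that attribute's small-group exclusions, plus a
    Pearson chi-square test (no continuity correction) of group-label
    independence. Continuous covariates are compared between label
    classes with two-sided Mann-Whitney tests. A chi-square test whose
    contingency table has a zero row or column margin is skipped with a
    warning recorded in the report.
    """
    specs = list(attribute_specs) if attribute_specs is not None \
        else default_attribute_specs()
    labels = list(label_definitions) if label_definitions is not None \
        else default_label_definitions()

    comp_rows: list[dict] = []
    chi_rows: list[dict] = []
    exclusions: list[dict] = []
    n_tests = 0

    for spec in specs:
        filtered, log = apply_exclusions(table, spec)
        exclusions.extend(log)
        for ldef in labels:
            y = ldef.realize(filtered)
            ok = y.notna()
            sub = filtered[ok]
            yv = y[ok].astype(int)
            groups = sub[spec.name]
            for level, idx in sub.groupby(groups, observed=True).indices.items():
                n = len(idx)
                pos = int(yv.iloc[idx].sum())
                comp_rows.append({
                    "attribute": spec.name, "group": str(level), "label": ldef.name,
                    "n": n, "n_positive": pos,
                    "selection_rate": pos / n if n else np.nan,
                })
            ct = pd.crosstab(groups, yv)
            warning = None
            if ct.shape[0] < 2 or ct.shape[1] < 2 or \
                    (ct.sum(axis=0) == 0).any() or (ct.sum(axis=1) == 0).any():
                warning = "degenerate contingency table; test skipped"
                stat = dof = pval = np.nan
            else:
                stat, pval, dof, expected = stats.chi2_contingency(
                    ct.to_numpy(), correction=False)
                n_tests += 1
                if (expected < 5).any():
                    warning = "expected cell count < 5; chi-square approximation fragile"
                    warnings.warn(
                        f"{spec.name} x {ldef.name}: {warning}",
                        SmallExpectedCountWarning, stacklevel=2)
            chi_rows.append({
                "attribute": spec.name, "label": ldef.name,
                "statistic": float(stat) if stat == stat else np.nan,
                "dof": int(dof) if dof == dof else np.nan,
                "p_value": float(pval) if pval == pval else np.nan,
                "significant": bool(pval < alpha) if pval == pval else None,
                "warning": warning,
            })

    cov_rows: list[dict] = []
    for ldef in labels:
        y = ldef.realize(table)
        for cov in covariates:
            if cov not in table.columns:
                continue
            mask = y.notna() & table[cov].notna()
            a = table.loc[mask & (y == 1), cov].to_numpy(float)
            b = table.loc[mask & (y == 0), cov].to_numpy(float)
            if a.size == 0 or b.size == 0:
                cov_rows.append({"covariate": cov, "label": ldef.name,
                                 "p_value": np.nan, "significant": None})
                continue
            p = mann_whitney(a, b)
            n_tests += 1
            cov_rows.append({"covariate": cov, "label": ldef.name,
                             "p_value": p, "significant": bool(p < alpha)})

    return AuditReport(
        composition=pd.DataFrame(comp_rows),
        chi_square=pd.DataFrame(chi_rows),
        covariate_tests=pd.DataFrame(cov_rows),
        exclusions=exclusions,
        alpha=alpha,
        n_tests=n_tests,
    )
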