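"""Group-fairness ratio metrics for binary classifiers.

Implements the four ratio metrics used to audit a classifier across the
levels of a sensitive attribute ``k`` with groups ``G`` and a designated
privileged group ``g*``:

- overall demographic parity ratio      ``D_k  = min_g S_g / max_g S_g``
- privilege-referenced parity ratio     ``D_g* = min_{g != g*} S_g / S_g*``
- overall equalized odds ratio          ``O_k  = min((min TPR + d)/(max TPR + d),
                                                     (min FPR + d)/(max FPR + d))``
- privilege-referenced equalized odds   ``O_g* = min(min_{g != g*} (TPR_g + d)/(TPR_g* + d),
                                                     min_{g != g*} (FPR_g* + d)/(FPR_g + d))``

where ``S_g`` is the selection rate (fraction of group ``g`` classified
positive), and ``d`` (``delta``) is an additive smoothing constant, default
0.001, that keeps the equalized-odds ratios finite when a rate is zero.
A value of 1 means parity; values further from 1 mean larger disparity.

Note the privilege-referenced equalized-odds ratio is intentionally
asymmetric: the privileged TPR sits in the denominator of the TPR term
while the privileged FPR sits in the numerator of the FPR term, so both
terms fall below 1 when the unprivileged group has *lower* TPR and
*higher* FPR than the privileged group. Either term (and hence the ratio)
may exceed 1 when the disparity runs the other way; values are reported
unclipped, with :func:`symmetric_disparity` available as a ``min(x, 1/x)``
summary.

Undefined rates (a group with no positives has no TPR; no negatives, no
FPR; an empty group has neither) are represented as ``None`` and excluded
from the ratios with a warning — they are never coerced to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupRates",
    "FairnessRatios",
    "UndefinedMetricWarning",
    "compute_group_rates",
    "dpr_overall",
    "dpr_privileged",
    "eor_overall",
    "eor_privileged",
    "compute_fairness_ratios",
    "macro_f1",
    "symmetric_disparity",
    "DEFAULT_DELTA",
]

DEFAULT_DELTA = 0.001


class UndefinedMetricWarning(UserWarning):
    """A rate or ratio could not be computed (zero denominator / empty group)."""


def _binary_f1(tp: int, fp: int, fn: int) -> float:
    """F1 for one class from its confusion counts.

    Zero-support conventions: a class absent from both truth and
    predictions (tp=fp=fn=0) scores 1; absent from truth but predicted
    (fp>0, tp=fn=0) scores 0.
    """
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def macro_f1(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Unweighted mean of the two per-class F1 scores of a binary classifier."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    f1_pos = _binary_f1(tp, fp, fn)
    f1_neg = _binary_f1(tn, fn, fp)  # negative class: tn are its "hits"
    return 0.5 * (f1_pos + f1_neg)


@dataclass(frozen=True)
class GroupRates:
    """Confusion counts and derived rates for one demographic group.

    ``tpr`` is ``None`` when the group contains no positive subjects,
    ``fpr`` is ``None`` when it contains no negatives; both flags are
    explicit rather than silent zeros.
    """

    group: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def selection_rate(self) -> float | None:
        return (self.tp + self.fp) / self.n if self.n > 0 else None

    @property
    def tpr(self) -> float | None:
        return self.tp / self.n_positive if self.n_positive > 0 else None

    @property
    def fpr(self) -> float | None:
        return self.fp / self.n_negative if self.n_negative > 0 else None

    @property
    def macro_f1(self) -> float | None:
        if self.n == 0:
            return None
        return 0.5 * (_binary_f1(self.tp, self.fp, self.fn)
                      + _binary_f1(self.tn, self.fn, self.fp))


@dataclass(frozen=True)
class FairnessRatios:
    """The four ratio metrics for one sensitive attribute.

    ``None`` marks a ratio that was undefined for the given groups
    (e.g. all selection rates zero, or fewer than two groups with
    defined error rates).
    """

    attribute: str
    privileged: str
    delta: float = DEFAULT_DELTA
    dpr_overall: float | None = None
    dpr_privileged: float | None = None
    eor_overall: float | None = None
    eor_privileged: float | None = None
    warnings: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float | None]:
        return {
            "dpr_overall": self.dpr_overall,
            "dpr_privileged": self.dpr_privileged,
            "eor_overall": self.eor_overall,
            "eor_privileged": self.eor_privileged,
        }


def compute_group_rates(
    frame: pd.DataFrame,
    attribute: str,
    *,
    y_true: str = "y_true",
    y_pred: str = "y_pred",
) -> dict[str, GroupRates]:
    """Confusion counts per level of ``attribute`` in a prediction table.

    Rows with a missing attribute value are dropped for this attribute.
    Raises ``ValueError`` on an empty table or missing columns.
    """
    for col in (attribute, y_true, y_pred):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not present in prediction table")
    sub = frame.dropna(subset=[attribute])
    if sub.empty:
        raise ValueError(f"no rows with a defined {attribute!r} value")
    yt = sub[y_true].to_numpy(dtype=int)
    yp = sub[y_pred].to_numpy(dtype=int)
    out: dict[str, GroupRates] = {}
    for g, idx in sub.groupby(attribute, observed=True).indices.items():
        t, p = yt[idx], yp[idx]
        out[str(g)] = GroupRates(
            group=str(g),
            tp=int(np.sum((t == 1) & (p == 1))),
            fp=int(np.sum((t == 0) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )
    return out


def _defined(values: Mapping[str, float | None]) -> dict[str, float]:
    return {g: v for g, v in values.items() if v is not None}


def dpr_overall(selection_rates: Mapping[str, float | None]) -> float | None:
    """Overall demographic parity ratio: min_g S_g / max_g S_g."""
    rates = _defined(selection_rates)
    if len(rates) < 2:
        warnings.warn("fewer than 2 groups with defined selection rates",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    hi = max(rates.values())
    if hi == 0:
        warnings.warn("all selection rates are zero; overall DPR undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    return min(rates.values()) / hi


def dpr_privileged(
    selection_rates: Mapping[str, float | None], privileged: str
) -> float | None:
    """Privilege-referenced parity ratio: min_{g != g*} S_g / S_g*.

    No smoothing is applied (smoothing belongs to the equalized-odds
    ratios only); the value may exceed 1 when every unprivileged rate
    exceeds the privileged one.
    """
    rates = _defined(selection_rates)
    if privileged not in rates:
        warnings.warn(f"privileged group {privileged!r} has no defined selection rate",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    others = [v for g, v in rates.items() if g != privileged]
    if not others:
        warnings.warn("no unprivileged group with a defined selection rate",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    s_star = rates[privileged]
    if s_star == 0:
        warnings.warn("privileged selection rate is zero; ratio undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    return min(others) / s_star


def _error_rates(
    group_rates: Mapping[str, GroupRates],
) -> tuple[dict[str, float], dict[str, float]]:
    """Groups with both TPR and FPR defined; others dropped with a warning."""
    tprs: dict[str, float] = {}
    fprs: dict[str, float] = {}
    for g, gr in group_rates.items():
        if gr.tpr is None or gr.fpr is None:
            which = "TPR" if gr.tpr is None else "FPR"
            warnings.warn(
                f"group {g!r} has undefined {which}; dropped from equalized-odds ratio",
                UndefinedMetricWarning, stacklevel=3)
            continue
        tprs[g] = gr.tpr
        fprs[g] = gr.fpr
    return tprs, fprs


def eor_overall(
    group_rates: Mapping[str, GroupRates], delta: float = DEFAULT_DELTA
) -> float | None:
    """Overall equalized odds ratio with additive delta smoothing."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    tprs, fprs = _error_rates(group_rates)
    if len(tprs) < 2:
        warnings.warn("fewer than 2 groups with defined TPR and FPR",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    t = list(tprs.values())
    f = list(fprs.values())
    return min(
        (min(t) + delta) / (max(t) + delta),
        (min(f) + delta) / (max(f) + delta),
    )


def eor_privileged(
    group_rates: Mapping[str, GroupRates],
    privileged: str,
    delta: float = DEFAULT_DELTA,
) -> float | None:
    """Privilege-referenced equalized odds ratio.

    Implements the printed orientation exactly: the privileged TPR in
    the denominator of the TPR term, the privileged FPR in the
    numerator of the FPR term. Not clipped to [0, 1].
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    tprs, fprs = _error_rates(group_rates)
    if privileged not in tprs:
        warnings.warn(f"privileged group {privileged!r} has undefined rates",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    others = [g for g in tprs if g != privileged]
    if not others:
        warnings.warn("no unprivileged group with defined rates",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    t_star, f_star = tprs[privileged], fprs[privileged]
    tpr_term = min((tprs[g] + delta) / (t_star + delta) for g in others)
    fpr_term = min((f_star + delta) / (fprs[g] + delta) for g in others)
    return min(tpr_term, fpr_term)


def symmetric_disparity(ratio: float | None) -> float | None:
    """Fold a ratio into [0, 1] as min(x, 1/x) — an extension, clearly not
    one of the four printed metrics, for summarizing >1 privilege-referenced
    values on the same "further from 1 is worse" scale."""
    if ratio is None:
        return None
    if ratio == 0:
        return 0.0
    return min(ratio, 1.0 / ratio)


def compute_fairness_ratios(
    frame: pd.DataFrame,
    attribute: str,
    privileged: str,
    delta: float = DEFAULT_DELTA,
    *,
    y_true: str = "y_true",
    y_pred: str = "y_pred",
) -> FairnessRatios:
    """All four ratios for one attribute of a prediction table."""
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", UndefinedMetricWarning)
        rates = compute_group_rates(frame, attribute, y_true=y_true, y_pred=y_pred)
        sel = {g: gr.selection_rate for g, gr in rates.items()}
        result = FairnessRatios(
            attribute=attribute,
            privileged=privileged,
            delta=delta,
            dpr_overall=dpr_overall(sel),
            dpr_privileged=dpr_privileged(sel, privileged),
            eor_overall=eor_overall(rates, delta),
            eor_privileged=eor_privileged(rates, privileged, delta),
            warnings=tuple(str(w.message) for w in caught
                           if issubclass(w.category, UndefinedMetricWarning)),
        )
    for w in caught:
        if not issubclass(w.category, UndefinedMetricWarning):
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    notes.extend(result.warnings)
    return result
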