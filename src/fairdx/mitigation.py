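"""Post-training equalized-odds threshold optimization.

Given a trained scorer, a sensitive attribute partitions subjects into
groups whose score distributions — and hence ROC curves — differ. The
derived-predictor construction (Hardt et al.'s post-processing method)
replaces the single decision threshold with one *randomized* decision
rule per group so that every group operates at a common (FPR, TPR)
point, i.e. the predictor satisfies equalized odds exactly on the data
it was fitted to, while overall accuracy is maximized subject to that
constraint.

Geometry: with randomization over thresholds, a group can realize any
point in the convex hull of its ROC operating points (the hull always
contains the diagonal, because predicting positive with a fixed
probability ignores the score). The feasible equalized-odds region is
the intersection of the groups' hulls; since the upper boundary of each
hull is a concave function of FPR, the intersection's upper boundary at
a given FPR ``x`` is simply ``min_g hull_g(x)``. Expected accuracy at an
operating point is ``pi * TPR + (1 - pi) * (1 - FPR)`` with ``pi`` the
pooled prevalence, so the optimum is found by scanning FPR on a grid and
maximizing that linear functional along the boundary (an interior point
is never optimal for ``0 < pi < 1``).

Realizing the common target for one group uses at most three primitive
classifiers: the two deterministic thresholds whose ROC vertices bracket
the target FPR on the group's hull (mixed with weight ``weight_lo``),
plus — when the target lies strictly *below* the group's hull, as it
does for every group not attaining the min — a score-independent coin
that predicts positive with probability equal to the target FPR, mixed
in with probability ``p_ignore``. Two thresholds alone can only reach
the hull boundary; the coin reaches the interior.

The scikit-learn-style :class:`EqualizedOddsThresholdOptimizer` wraps
:func:`fit_eo_policy` / :func:`apply_policy` for pipeline use.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve

__all__ = [
    "RocCurve",
    "GroupPolicy",
    "ThresholdPolicy",
    "build_roc",
    "fit_eo_policy",
    "apply_policy",
    "EqualizedOddsThresholdOptimizer",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID_RESOLUTION = 0.001


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points of one group, with their upper convex hull.

    Points are ordered by nondecreasing FPR and always include (0, 0)
    (threshold above every score) and (1, 1) (threshold at or below the
    minimum score). ``hull`` indexes the vertices of the upper convex
    hull, a concave chain from (0, 0) to (1, 1). ``degenerate`` marks a
    group whose data contained a single class, for which no curve is
    defined.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    hull: np.ndarray
    degenerate: bool = False

    def hull_height(self, x: float | np.ndarray) -> float | np.ndarray:
        """TPR of the upper hull at the given FPR (piecewise linear)."""
        if self.degenerate:
            raise ValueError("degenerate curve has no hull")
        hx, hy, _ = _dedup_hull(self.fpr[self.hull], self.tpr[self.hull],
                                self.thresholds[self.hull])
        return np.interp(x, hx, hy)


def _dedup_hull(hx: np.ndarray, hy: np.ndarray, ht: np.ndarray):
    """Collapse hull vertices sharing an FPR to the highest-TPR one.

    The upper hull may start with a vertical edge at FPR = 0 (e.g. a
    partially separable group); interpolation and vertex bracketing need
    strictly increasing x, and the top of the edge dominates.
    """
    keep = np.r_[hx[1:] > hx[:-1], True]
    return hx[keep], hy[keep], ht[keep]


def _upper_hull(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    """Indices of the upper convex hull by the monotone-chain method.

    Input points must be sorted by (fpr, tpr); collinear points are
    dropped so hull vertices form a strictly concave-down chain.
    """
    hull: list[int] = []
    for i in range(len(fpr)):
        while len(hull) >= 2:
            ox, oy = fpr[hull[-2]], tpr[hull[-2]]
            ax, ay = fpr[hull[-1]], tpr[hull[-1]]
            cross = (ax - ox) * (tpr[i] - oy) - (ay - oy) * (fpr[i] - ox)
            if cross >= 0:  # right turn or collinear: pop
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def build_roc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and upper convex hull of a score vector.

    Single-class input yields a degenerate marker rather than an
    exception (callers decide whether to fall back). The decision rule
    associated with threshold ``t`` is ``score >= t``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        return RocCurve(np.array([]), np.array([]), np.array([]),
                        np.array([], dtype=int), degenerate=True)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    order = np.lexsort((tpr, fpr))
    fpr, tpr, thr = fpr[order], tpr[order], thr[order]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, hull=_upper_hull(fpr, tpr))


@dataclass(frozen=True)
class GroupPolicy:
    """Randomized decision rule of one group.

    With probability ``p_ignore`` the score is ignored and the
    prediction is positive with probability ``target_fpr`` (realizing
    the diagonal point); otherwise the rule thresholds the score at
    ``t_lo`` with probability ``weight_lo`` and at ``t_hi`` with
    probability ``1 - weight_lo`` (``score >= t`` predicts positive).
    """

    group: str
    t_lo: float
    t_hi: float
    weight_lo: float
    p_ignore: float = 0.0
    fallback: bool = False
    achieved_fpr: float = float("nan")
    achieved_tpr: float = float("nan")


@dataclass
class ThresholdPolicy:
    """Per-group randomized thresholds realizing a common (FPR, TPR) target."""

    target_fpr: float
    target_tpr: float
    grid_resolution: float
    prevalence: float
    expected_accuracy: float
    groups: dict[str, GroupPolicy] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "target_fpr": self.target_fpr,
            "target_tpr": self.target_tpr,
            "grid_resolution": self.grid_resolution,
            "prevalence": self.prevalence,
            "expected_accuracy": self.expected_accuracy,
            "seed": self.seed,
            "groups": {g: asdict(p) for g, p in self.groups.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ThresholdPolicy":
        data = json.loads(text)
        groups = {g: GroupPolicy(**p) for g, p in data.pop("groups").items()}
        return cls(groups=groups, **data)


def _pooled_best_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Single accuracy-maximizing threshold on pooled data (fallback rule)."""
    curve = build_roc(scores, labels)
    if curve.degenerate:
        # all one class: predict it everywhere
        return -np.inf if labels[0] == 1 else np.inf
    pi = labels.mean()
    acc = pi * curve.tpr + (1 - pi) * (1 - curve.fpr)
    return float(curve.thresholds[int(np.argmax(acc))])


def fit_eo_policy(
    scores: Sequence[float],
    labels: Sequence[int],
    groups: Sequence,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION,
    seed: int | None = None,
) -> ThresholdPolicy:
    """Learn per-group randomized thresholds under an equalized-odds constraint.

    Scans FPR on a grid of step ``grid_resolution``; at each grid value
    ``x`` the highest TPR every group can reach is ``min_g hull_g(x)``,
    and the target maximizing expected accuracy (pooled prevalence) is
    selected, ties broken toward smaller FPR. Each group's rule then
    realizes the target exactly on the fitting data (see module notes).

    Groups whose fitting data contain a single class cannot support a
    curve; they fall back to the pooled accuracy-optimal single
    threshold, logged and flagged on the policy.
    """
    if not 0 < grid_resolution <= 0.1:
        raise ValueError("grid_resolution must be in (0, 0.1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    if not (len(scores) == len(labels) == len(groups)):
        raise ValueError("scores, labels and groups must have equal length")

    curves: dict[str, RocCurve] = {}
    degenerate: list[str] = []
    for g in pd.unique(groups):
        mask = groups == g
        curve = build_roc(scores[mask], labels[mask])
        if curve.degenerate:
            degenerate.append(str(g))
        else:
            curves[str(g)] = curve
    if not curves:
        raise ValueError("no group with both classes present; cannot fit")
    if degenerate:
        logger.info("degenerate groups %s fall back to the pooled threshold",
                    degenerate)

    active = np.isin(groups.astype(str), list(curves))
    pi = float(labels[active].mean())

    grid = np.arange(0.0, 1.0 + grid_resolution / 2, grid_resolution)
    grid = np.clip(grid, 0.0, 1.0)
    heights = np.min([c.hull_height(grid) for c in curves.values()], axis=0)
    # feasibility: the diagonal is always achievable, so heights >= grid
    assert np.all(heights >= grid - 1e-12), "hull fell below the diagonal"
    acc = pi * heights + (1 - pi) * (1 - grid)
    best = int(np.argmax(acc))  # first max -> smallest fpr on ties
    fpr_star = float(grid[best])
    tpr_star = float(heights[best])

    policy = ThresholdPolicy(
        target_fpr=fpr_star,
        target_tpr=tpr_star,
        grid_resolution=grid_resolution,
        prevalence=pi,
        expected_accuracy=float(acc[best]),
        seed=seed,
    )

    for g, curve in curves.items():
        hx, hy, ht = _dedup_hull(curve.fpr[curve.hull], curve.tpr[curve.hull],
                                 curve.thresholds[curve.hull])
        j = int(np.searchsorted(hx, fpr_star, side="right"))
        j = min(max(j, 1), len(hx) - 1)
        f_l, f_r = hx[j - 1], hx[j]
        w_r = 0.0 if f_r == f_l else (fpr_star - f_l) / (f_r - f_l)
        w_r = float(np.clip(w_r, 0.0, 1.0))
        hull_tpr = (1 - w_r) * hy[j - 1] + w_r * hy[j]
        # interior target: mix with the score-independent diagonal point
        if hull_tpr - tpr_star > 1e-12 and hull_tpr - fpr_star > 1e-12:
            p_ignore = float((hull_tpr - tpr_star) / (hull_tpr - fpr_star))
        else:
            p_ignore = 0.0
        ach_fpr = fpr_star
        ach_tpr = (1 - p_ignore) * hull_tpr + p_ignore * fpr_star
        policy.groups[g] = GroupPolicy(
            group=g,
            t_lo=float(ht[j]),      # higher-FPR vertex = lower threshold
            t_hi=float(ht[j - 1]),
            weight_lo=w_r,
            p_ignore=p_ignore,
            achieved_fpr=float(ach_fpr),
            achieved_tpr=float(ach_tpr),
        )

    if degenerate:
        t_pool = _pooled_best_threshold(scores[active], labels[active])
        for g in degenerate:
            policy.groups[g] = GroupPolicy(
                group=g, t_lo=t_pool, t_hi=t_pool, weight_lo=1.0,
                fallback=True)
    return policy


def _row_rng(seed: int, subject_id) -> np.random.Generator:
    """Reproducible per-row stream keyed by (seed, subject id), so
    predictions do not depend on table order."""
    digest = hashlib.sha256(str(subject_id).encode()).digest()
    h = int.from_bytes(digest[:8], "big") & (2**63 - 1)
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


def apply_policy(
    policy: ThresholdPolicy,
    scores: Sequence[float],
    groups: Sequence,
    seed: int | None = None,
    subject_ids: Sequence | None = None,
    allow_fallback: bool = True,
) -> np.ndarray:
    """Predict labels from scores under a fitted per-group policy.

    Deterministic given (policy, scores, groups, seed); randomization is
    keyed per row by (seed, subject id) so row order is irrelevant. Rows
    from a group absent from the policy use the policy's fallback
    threshold when ``allow_fallback`` and any fallback exists, else an
    error names the group. With degenerate mixtures (``weight_lo`` 0 or
    1 and ``p_ignore`` 0) the rule reduces to plain thresholding.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    n = len(scores)
    if subject_ids is None:
        subject_ids = np.arange(n)
    if seed is None:
        seed = policy.seed if policy.seed is not None else 0
    fallbacks = [p for p in policy.groups.values() if p.fallback]
    out = np.empty(n, dtype=int)
    for i in range(n):
        g = str(groups[i])
        gp = policy.groups.get(g)
        if gp is None:
            if allow_fallback and fallbacks:
                gp = fallbacks[0]
            elif allow_fallback:
                gp = GroupPolicy(group=g, t_lo=0.5, t_hi=0.5, weight_lo=1.0,
                                 fallback=True)
            else:
                raise ValueError(f"group {g!r} not covered by the policy")
        rng = _row_rng(seed, subject_ids[i])
        u_ignore, u_mix = rng.random(2)
        if gp.p_ignore > 0 and u_ignore < gp.p_ignore:
            out[i] = int(rng.random() < policy.target_fpr)
        else:
            t = gp.t_lo if u_mix < gp.weight_lo else gp.t_hi
            out[i] = int(scores[i] >= t)
    return out


class EqualizedOddsThresholdOptimizer(BaseEstimator):
    """Scikit-learn style wrapper around the derived-predictor fit.

    Parameters
    ----------
    grid_resolution : float, default 0.001
        Step of the FPR grid scanned for the accuracy-optimal common
        operating point; bounds the optimality loss.
    random_state : int or None
        Seed for the randomized decision rule at predict time.

    Attributes (after ``fit``)
    --------------------------
    policy_ : ThresholdPolicy
    target_fpr_, target_tpr_ : float
        The common operating point all groups are driven to.
    expected_accuracy_ : float
        Expected accuracy of the randomized predictor on the fit data.

    Examples
    --------
    >>> opt = EqualizedOddsThresholdOptimizer(grid_resolution=0.01)
    >>> opt.fit(scores, y, sensitive_features=gender)       # doctest: +SKIP
    >>> y_fair = opt.predict(scores, sensitive_features=gender)  # doctest: +SKIP
    """

    def __init__(self, grid_resolution: float = DEFAULT_GRID_RESOLUTION,
                 random_state: int | None = None):
        self.grid_resolution = grid_resolution
        self.random_state = random_state

    def fit(self, X, y, *, sensitive_features):
        scores = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=int)
        if scores.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.policy_ = fit_eo_policy(
            scores, y, np.asarray(sensitive_features),
            grid_resolution=self.grid_resolution, seed=self.random_state)
        self.target_fpr_ = self.policy_.target_fpr
        self.target_tpr_ = self.policy_.target_tpr
        self.expected_accuracy_ = self.policy_.expected_accuracy
        return self

    def predict(self, X, *, sensitive_features, subject_ids=None):
        if not hasattr(self, "policy_"):
            raise AttributeError("optimizer is not fitted")
        scores = np.asarray(X, dtype=float).reshape(-1)
        return apply_policy(self.policy_, scores,
                            np.asarray(sensitive_features),
                            seed=self.random_state, subject_ids=subject_ids)
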