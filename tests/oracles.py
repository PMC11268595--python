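"""Independent naive oracles used by the test suite.

These are deliberately plain transcriptions — per-group counting with
explicit loops, min/max arithmetic, and exhaustive enumeration — kept
free of any code path shared with the package so that agreement between
the two routes is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def naive_group_stats(df, attr):
    """Selection rate, TPR, FPR per group by direct counting."""
    out = {}
    for g in sorted(df[attr].astype(str).unique()):
        sub = df[df[attr].astype(str) == g]
        n = len(sub)
        sel = tpr = fpr = None
        if n:
            sel = float((sub["y_pred"] == 1).mean())
            pos = sub[sub["y_true"] == 1]
            neg = sub[sub["y_true"] == 0]
            if len(pos):
                tpr = float((pos["y_pred"] == 1).mean())
            if len(neg):
                fpr = float((neg["y_pred"] == 1).mean())
        out[g] = {"S": sel, "TPR": tpr, "FPR": fpr, "n": n}
    return out


def naive_ratios(stats, privileged, delta=0.001):
    """Direct transcription of the four printed ratio formulas."""
    S = {g: v["S"] for g, v in stats.items() if v["S"] is not None}
    both = {g: (v["TPR"], v["FPR"]) for g, v in stats.items()
            if v["TPR"] is not None and v["FPR"] is not None}
    out = {}
    out["dpr_overall"] = (min(S.values()) / max(S.values())
                          if len(S) >= 2 and max(S.values()) > 0 else None)
    if privileged in S and S[privileged] > 0 and \
            any(g != privileged for g in S):
        out["dpr_privileged"] = min(
            v for g, v in S.items() if g != privileged) / S[privileged]
    else:
        out["dpr_privileged"] = None
    if len(both) >= 2:
        tprs = [t for t, _ in both.values()]
        fprs = [f for _, f in both.values()]
        out["eor_overall"] = min(
            (min(tprs) + delta) / (max(tprs) + delta),
            (min(fprs) + delta) / (max(fprs) + delta))
    else:
        out["eor_overall"] = None
    if privileged in both and any(g != privileged for g in both):
        t_star, f_star = both[privileged]
        others = [g for g in both if g != privileged]
        out["eor_privileged"] = min(
            min((both[g][0] + delta) / (t_star + delta) for g in others),
            min((f_star + delta) / (both[g][1] + delta) for g in others))
    else:
        out["eor_privileged"] = None
    return out


def naive_macro_f1(y_true, y_pred):
    """Macro F1 by per-class precision/recall with explicit conventions:
    a class missing from truth and predictions scores 1, missing from
    truth but predicted scores 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    f1s = []
    for c in (0, 1):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        in_truth = int(np.sum(y_true == c))
        in_pred = int(np.sum(y_pred == c))
        if in_truth == 0 and in_pred == 0:
            f1s.append(1.0)
            continue
        prec = tp / in_pred if in_pred else 0.0
        rec = tp / in_truth if in_truth else 0.0
        f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    return float(np.mean(f1s))


def random_prediction_table(rng, n_groups=None, rows_per_group=(5, 50)):
    """A random small prediction table for oracle-equivalence checks."""
    import pandas as pd

    n_groups = n_groups or int(rng.integers(2, 5))
    rows = []
    for gi in range(n_groups):
        n = int(rng.integers(rows_per_group[0], rows_per_group[1] + 1))
        y = rng.integers(0, 2, n)
        yp = rng.integers(0, 2, n)
        for i in range(n):
            rows.append({"subject_id": f"g{gi}_{i}", "repeat": 1, "fold": 1,
                         "y_true": int(y[i]), "score": float(rng.random()),
                         "y_pred": int(yp[i]), "grp": f"g{gi}"})
    return pd.DataFrame(rows)


# -- exhaustive enumeration oracle for the equalized-odds optimizer --------


def _threshold_points(scores, labels):
    """All single-threshold operating points (rule: score >= t)."""
    thresholds = np.concatenate(
        [[np.inf], np.unique(scores)[::-1], [-np.inf]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    pts = []
    for t in thresholds:
        tpr = float(np.mean(pos >= t)) if len(pos) else 0.0
        fpr = float(np.mean(neg >= t)) if len(neg) else 0.0
        pts.append((fpr, tpr))
    return pts


def _mixture_cloud(scores, labels, weight_step=0.01):
    """Every two-threshold mixture at the given weight grid."""
    pts = _threshold_points(scores, labels)
    ws = np.arange(0.0, 1.0 + weight_step / 2, weight_step)
    cloud = []
    for i in range(len(pts)):
        f1, t1 = pts[i]
        for j in range(i, len(pts)):
            f2, t2 = pts[j]
            for w in ws:
                cloud.append((w * f1 + (1 - w) * f2, w * t1 + (1 - w) * t2))
    return np.asarray(cloud)


def brute_force_eo_accuracy(scores, labels, groups, weight_step=0.01,
                            fpr_bin=0.002):
    """Best accuracy achievable with all groups at a common operating
    point, by exhaustive enumeration of two-threshold mixtures.

    For each candidate point (drawn from every group's mixture cloud),
    the highest TPR each group can reach at that FPR is looked up in a
    binned index of its own cloud; the common TPR is the minimum, and
    accuracy is pi * tpr + (1 - pi) * (1 - fpr).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    groups = np.asarray(groups).astype(str)
    pi = labels.mean()
    n_bins = int(round(1.0 / fpr_bin)) + 1
    clouds = {}
    binned = {}
    for g in np.unique(groups):
        m = groups == g
        cloud = _mixture_cloud(scores[m], labels[m], weight_step)
        clouds[g] = cloud
        top = np.full(n_bins, -np.inf)
        idx = np.clip(np.rint(cloud[:, 0] / fpr_bin).astype(int), 0, n_bins - 1)
        np.maximum.at(top, idx, cloud[:, 1])
        binned[g] = top

    def max_tpr_at(g, f):
        i = int(np.clip(round(f / fpr_bin), 0, n_bins - 1))
        lo, hi = max(i - 1, 0), min(i + 2, n_bins)
        return np.max(binned[g][lo:hi])

    best = -np.inf
    candidate_fprs = np.unique(np.clip(np.rint(np.concatenate(
        [c[:, 0] for c in clouds.values()]) / fpr_bin), 0, n_bins - 1)) * fpr_bin
    for f in candidate_fprs:
        common = min(max_tpr_at(g, f) for g in clouds)
        best = max(best, pi * common + (1 - pi) * (1 - f))
    return float(best)


def permutation_chi2_p(groups, y, n_perm=10000, rng=None,
                       return_null=False):
    """Permutation-null p-value for the Pearson chi-square statistic,
    permuting labels against fixed group memberships. With
    ``return_null`` also returns the observed statistic and the sampled
    null statistics (the null is discrete; callers comparing against a
    continuous approximation need the atom around the observed value)."""
    rng = rng or np.random.default_rng(0)
    groups = np.asarray(groups)
    y = np.asarray(y, int)
    levels = np.unique(groups)
    onehot = (groups[:, None] == levels[None, :]).astype(float)
    totals = onehot.sum(0)
    n = len(y)

    def stat(yvec):
        pos = yvec @ onehot
        ct = np.stack([totals - pos, pos])  # 2 x G
        e = (ct.sum(1, keepdims=True) * ct.sum(0, keepdims=True)) / n
        return float(((ct - e) ** 2 / e).sum())

    obs = stat(y.astype(float))
    perms = np.tile(y.astype(float), (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    pos = perms @ onehot  # n_perm x G
    ct1 = pos
    ct0 = totals[None, :] - pos
    col = np.stack([ct0, ct1], axis=1)  # n_perm x 2 x G
    row_tot = col.sum(axis=2, keepdims=True)
    col_tot = col.sum(axis=1, keepdims=True)
    e = row_tot * col_tot / n
    stats = ((col - e) ** 2 / e).sum(axis=(1, 2))
    p = (1 + np.sum(stats >= obs - 1e-12)) / (n_perm + 1)
    if return_null:
        return p, obs, stats
    return p
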