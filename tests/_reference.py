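"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (literal replays, brute-force scans,
exact enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def replay_marker_selection(F, c, alpha, beta):
    """Literal line-by-line replay of the marker-selection pseudocode.

    Iterates markers most-significant first (ascending KS p-value, ties
    lexicographic), inner loop over not-yet-analysed markers, excluding the
    higher-p member of each |r| > beta pair.  Returns the surviving set.
    """
    c = np.asarray(c)
    mask1 = c == c.max()
    cols = {m: F[m].to_numpy(dtype=float) for m in F.columns}
    pcache = {}

    def pval(m):
        if m not in pcache:
            pcache[m] = stats.ks_2samp(cols[m][~mask1], cols[m][mask1]).pvalue
        return pcache[m]

    marker_set = sorted(F.columns, key=lambda m: (pval(m), m))
    excluded = set()
    analysed = set()
    for m1 in marker_set:
        analysed.add(m1)
        if m1 in excluded:
            continue
        if pval(m1) > alpha:
            excluded.add(m1)
            continue
        for m2 in marker_set:
            if m2 in analysed or m2 in excluded:
                continue
            if pval(m2) > alpha:
                excluded.add(m2)
                continue
            x, y = cols[m1], cols[m2]
            if x.std() == 0 or y.std() == 0:
                pc = 0.0
            else:
                pc = abs(np.corrcoef(x, y)[0, 1])
            if pc > beta:
                if pval(m2) >= pval(m1):
                    excluded.add(m2)
                else:
                    excluded.add(m1)
                    break
    return [m for m in marker_set if m not in excluded]


def exact_ks_pvalue(a, b):
    """Exact two-sample KS p-value by enumerating all label assignments.

    Feasible for tiny samples only (used with n = m = 4: C(8,4) = 70 splits).
    Assumes no ties between observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def ks_stat(x, y):
        grid = np.sort(np.concatenate([x, y]))
        cx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
        cy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
        return np.abs(cx - cy).max()

    observed = ks_stat(a, b)
    count = total = 0
    for idx in combinations(range(n + m), n):
        xa = pooled[list(idx)]
        xb = pooled[[i for i in range(n + m) if i not in idx]]
        total += 1
        if ks_stat(xa, xb) >= observed - 1e-12:
            count += 1
    return count / total


def exhaustive_threshold(scores, labels):
    """Brute-force Youden-J threshold over midpoints of sorted unique scores."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == np.asarray(labels).max()
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]), 0.0
    best_thr, best_j = None, -np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        thr = (lo + hi) / 2.0
        pred = scores >= thr
        j = ((pred & pos).sum() / pos.sum()
             + (~pred & ~pos).sum() / (~pos).sum() - 1.0)
        if j > best_j:
            best_thr, best_j = thr, j
    return float(best_thr), float(best_j)


def mann_whitney_auc(labels, scores):
    """AUC from the Mann-Whitney U statistic with midrank tie handling."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def binary_log_loss(y, p, eps=1e-15):
    """Elementwise cross-entropy summed by explicit loop."""
    total = 0.0
    for yi, pi in zip(y, p):
        pi = min(max(pi, eps), 1.0 - eps)
        total += yi * np.log(pi) + (1.0 - yi) * np.log(1.0 - pi)
    return -total / len(y)
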