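"""Brute-force reference implementations used only to check the package.

Every oracle here is deliberately naive — O(n^2) pair counting,
exhaustive threshold walks, 2^n enumerations, power-set Shapley — and
shares no code with the implementation paths it validates.
"""

from __future__ import annotations

from itertools import combinations, product
from math import factorial

import numpy as np


def auroc_pair_counting(scores, labels) -> float:
    """Probability a random positive outscores a random negative, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_walk(scores, labels) -> float:
    """Step-wise precision/recall walk over descending unique thresholds.

    AP = sum over thresholds of (recall increment) * precision, which for
    distinct scores reduces to the mean of precision-at-k over positives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    thresholds = np.unique(scores)[::-1]
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        sel = scores >= t
        tp = int(((labels == 1) & sel).sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def wilcoxon_enumeration(x, y, direction) -> float:
    """Exact one-tailed signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum() if direction == "greater" else ranks[d < 0].sum()
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n


def mannwhitney_enumeration(x, y, direction) -> float:
    """Exact one-tailed Mann-Whitney p by enumerating label assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_stat(x, y) if direction == "greater" else u_stat(y, x)
    count = total = 0
    for idx in combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(n + m) if i not in set(idx)]]
        u = u_stat(xs, ys) if direction == "greater" else u_stat(ys, xs)
        total += 1
        if u >= u_obs - 1e-12:
            count += 1
    return count / total


def bh_stepup(pvalues) -> np.ndarray:
    """Hand step-up: sort, multiply by n/rank, cumulative-min from the top."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# Power-set Shapley over dumped trees
# ---------------------------------------------------------------------------


def tree_conditional_expectation(tree, x, coalition) -> float:
    """Path-dependent E[f(x_S)]: follow x on coalition features, cover-weight others."""

    def rec(node):
        if tree.feature[node] < 0:
            return float(tree.value[node])
        f = tree.feature[node]
        if f in coalition:
            child = (
                tree.children_yes[node]
                if np.float32(x[f]) < np.float32(tree.threshold[node])
                else tree.children_no[node]
            )
            return rec(child)
        yes, no = tree.children_yes[node], tree.children_no[node]
        w = tree.cover[yes] / tree.cover[node]
        return w * rec(yes) + (1 - w) * rec(no)

    return rec(0)


def shapley_powerset(trees, x, n_features) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^(n_features-1) coalitions."""
    phi = np.zeros(n_features)
    allf = list(range(n_features))
    for i in allf:
        others = [j for j in allf if j != i]
        for k in range(len(others) + 1):
            for S in combinations(others, k):
                w = factorial(k) * factorial(n_features - k - 1) / factorial(n_features)
                with_i = sum(tree_conditional_expectation(t, x, set(S) | {i}) for t in trees)
                without = sum(tree_conditional_expectation(t, x, set(S)) for t in trees)
                phi[i] += w * (with_i - without)
    return phi


def cohort_fraction_counting(percentiles):
    """(above-median, top-quartile, top-decile) fractions by direct counting."""
    p = list(percentiles)
    n = len(p)
    return (
        sum(1 for v in p if v < 0.5) / n,
        sum(1 for v in p if v <= 0.25) / n,
        sum(1 for v in p if v <= 0.10) / n,
    )
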