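"""Performance metrics, method comparison, and statistical tests.

auROC is the rank (Mann-Whitney) formulation: the probability that a
random positive outscores a random negative, with ties counted half.
auPRC is average precision with step interpolation — the sum of precision
at each recall increment — whose random baseline equals the positive-class
prevalence.  Both choices avoid the optimism of linear interpolation on
imbalanced data.

The tests mirror standard usage in model-comparison studies: one-tailed
paired Wilcoxon signed-rank (exact for n <= 25 via the subset-sum
distribution of tie-averaged ranks, normal approximation with continuity
correction beyond), one-tailed Mann-Whitney U, and Benjamini-Hochberg
step-up adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EvaluationReport:
    """auROC/auPRC of one scoring method on one tissue's labels."""

    tissue: str
    auroc: float
    auprc: float
    expected_auprc: float
    n_pos: int
    n_neg: int


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != labels.size:
        raise ValueError("labels must be binary 0/1")
    return n_pos, n_neg


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = _check_binary(np.asarray(labels))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC requires at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """Average precision and the prevalence baseline ``(ap, prevalence)``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_binary(labels)
    if n_pos == 0:
        raise ValueError("auPRC requires at least one positive")
    return float(average_precision_score(labels, scores)), n_pos / (n_pos + n_neg)


def evaluate(scores, labels, tissue: str = "") -> EvaluationReport:
    n_pos, n_neg = _check_binary(np.asarray(labels))
    ap, prev = auprc(scores, labels)
    return EvaluationReport(
        tissue=tissue,
        auroc=auroc(scores, labels),
        auprc=ap,
        expected_auprc=prev,
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# Shared-subset method comparison and the hybrid baseline
# ---------------------------------------------------------------------------


def compare_methods(
    our_scores: Mapping[str, float],
    other_scores: Mapping[str, Mapping[str, float]],
    labels: Mapping[str, int],
    tissue: str = "",
) -> dict[str, tuple[EvaluationReport, EvaluationReport]]:
    """Evaluate our model against each external method on its scored subset.

    For every method, both scorings are evaluated on the intersection of
    variants scored by that method and by us — our report is recomputed per
    subset, never reused.  Methods with an empty usable intersection are
    skipped with a warning.
    """
    import logging

    out: dict[str, tuple[EvaluationReport, EvaluationReport]] = {}
    ours = set(our_scores)
    for method, sc in other_scores.items():
        shared = sorted(ours & set(sc) & set(labels))
        y = np.array([labels[v] for v in shared])
        if not shared or y.sum() == 0 or y.sum() == len(y):
            logging.getLogger(__name__).warning(
                "method %s skipped: unusable score intersection (n=%d)", method, len(shared)
            )
            continue
        ours_rep = evaluate([our_scores[v] for v in shared], y, tissue)
        their_rep = evaluate([sc[v] for v in shared], y, tissue)
        out[method] = (ours_rep, their_rep)
    return out


def hybrid_score(variant_score: float, gene_tissue_score: float) -> float:
    """Post hoc hybrid baseline: arithmetic mean of a tissue-oblivious
    variant score and a tissue-aware gene score."""
    if variant_score is None or gene_tissue_score is None or np.isnan(variant_score) or np.isnan(gene_tissue_score):
        raise ValueError("hybrid_score requires both operands; filter missing scores upstream")
    return (float(variant_score) + float(gene_tissue_score)) / 2.0


# ---------------------------------------------------------------------------
# Wrong-tissue matrix and affected-tissue ranks
# ---------------------------------------------------------------------------


@dataclass
class CrossTissueMatrix:
    """auROC of each tissue model against each tissue's labels."""

    tissues: list[str]
    auroc_matrix: pd.DataFrame  # rows = model tissue, cols = label tissue


def cross_tissue_matrix(models, features, label_matrix, test_ids: Sequence[str]) -> CrossTissueMatrix:
    """Entry (m, t): auROC of model m's scores against tissue t's labels.

    Tissues whose test labels are single-class get NaN entries.
    """
    from .training import predict_scores

    tissues = list(models)
    sub = features.subset(test_ids)
    id_index = {vid: i for i, vid in enumerate(label_matrix.variant_ids)}
    rows = [id_index[v] for v in sub.variant_ids]
    mat = pd.DataFrame(np.nan, index=tissues, columns=tissues, dtype=float)
    score_of = {m: predict_scores(models[m], sub).scores for m in tissues}
    for t in tissues:
        y = label_matrix.column(t)[rows]
        if y.min() == y.max():
            continue
        for m in tissues:
            mat.loc[m, t] = auroc(score_of[m], y)
    return CrossTissueMatrix(tissues, mat)


def percentile_ranks(scores: np.ndarray) -> np.ndarray:
    """Percentile rank per item, rank 1 = highest score, ties averaged;
    percentile = rank / n (so smaller is better)."""
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(-scores, method="average")
    return ranks / scores.size


@dataclass
class AffectedTissueRanks:
    """Per-variant percentile ranks and per-tissue paired comparisons."""

    percentiles: pd.DataFrame  # rows = pathogenic test variants, cols = model tissue
    absolute_ranks: pd.DataFrame
    median_by_tissue: pd.DataFrame  # rows = affected tissue, cols = model tissue
    tests: pd.DataFrame  # columns: tissue, other_model, n, p, p_adj


def affected_tissue_ranks(models, features, label_matrix, test_ids: Sequence[str]) -> AffectedTissueRanks:
    """Rank pathogenic test variants under every tissue model.

    For each tissue t, the percentiles of t's pathogenic variants under
    the model of t are compared against their percentiles under every
    other model with a one-tailed paired Wilcoxon test (alternative: the
    affected-tissue model ranks them better, i.e. smaller percentile),
    Benjamini-Hochberg adjusted across all (tissue, other model) pairs.
    """
    from .training import predict_scores

    tissues = list(models)
    sub = features.subset(test_ids)
    id_index = {vid: i for i, vid in enumerate(label_matrix.variant_ids)}
    rows = np.array([id_index[v] for v in sub.variant_ids])
    lab = label_matrix.labels[rows][:, [label_matrix.tissues.index(t) for t in tissues]]
    path_mask = lab.any(axis=1)
    path_ids = [vid for vid, m in zip(sub.variant_ids, path_mask) if m]

    pct = pd.DataFrame(index=pd.Index(sub.variant_ids), columns=tissues, dtype=float)
    rk = pd.DataFrame(index=pd.Index(sub.variant_ids), columns=tissues, dtype=float)
    for t in tissues:
        s = predict_scores(models[t], sub).scores
        r = stats.rankdata(-s, method="average")
        rk[t] = r
        pct[t] = r / len(s)
    pct_path = pct.loc[path_ids]
    rk_path = rk.loc[path_ids]

    med_rows, test_rows = [], []
    for ti, t in enumerate(tissues):
        mine = pct_path[lab[path_mask][:, ti] == 1]
        if mine.empty:
            continue
        med_rows.append(pd.Series(mine.median(), name=t))
        for m in tissues:
            if m == t or len(mine) < 3:
                continue
            p = wilcoxon_paired_one_tailed(mine[t].to_numpy(), mine[m].to_numpy(), "less")
            test_rows.append({"tissue": t, "other_model": m, "n": len(mine), "p": p})
    tests = pd.DataFrame(test_rows)
    if len(tests):
        tests["p_adj"] = bh_adjust(tests["p"].to_numpy())
    median_by_tissue = pd.DataFrame(med_rows) if med_rows else pd.DataFrame(columns=tissues)
    return AffectedTissueRanks(pct_path, rk_path, median_by_tissue, tests)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

_EXACT_WILCOXON_MAX_N = 25


def wilcoxon_paired_one_tailed(x: Sequence[float], y: Sequence[float], direction: str) -> float:
    """One-tailed paired Wilcoxon signed-rank p-value.

    ``direction`` is the alternative for x relative to y: "greater" tests
    whether x tends to exceed y, "less" the reverse.  Zero differences are
    dropped (Wilcoxon convention).  Exact subset-sum distribution of the
    tie-averaged ranks for n <= 25; normal approximation with continuity
    and tie correction beyond.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if n < 3:
        raise ValueError("need >= 3 nonzero paired differences")
    ranks = stats.rankdata(np.abs(d), method="average")
    w_pos = float(ranks[d > 0].sum())
    if direction == "less":
        w_pos = float(ranks[d < 0].sum())  # tail on W- == tail on W+ of -d
    if n <= _EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_tail(ranks, w_pos)
    total = ranks.sum()
    mean = total / 2.0
    # variance with tie correction: sum(r^2)/4
    var = float((ranks**2).sum()) / 4.0
    z = (w_pos - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def _exact_signed_rank_tail(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) by dynamic programming over the 2^n sign assignments.

    Ranks are doubled so tie-averaged (half-integer) ranks become
    integers; the DP counts sign assignments per achievable doubled sum.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(np.ceil(round(w_obs * 2, 6) - 1e-9))
    tail = counts[w2:].sum()
    return float(tail / counts.sum())


def mannwhitney_one_tailed(x: Sequence[float], y: Sequence[float], direction: str) -> float:
    """One-tailed Mann-Whitney U p-value for x versus y.

    Exact when min(len(x), len(y)) <= 8 and there are no ties; otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: every observation tied
        return 0.5
    no_ties = np.unique(pooled).size == x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=direction, method=method)
    return float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
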