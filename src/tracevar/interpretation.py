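"""Shapley-additive interpretation of the tissue models.

Attributions are exact tree-path Shapley values computed in the model's
margin (log-odds) space, where local accuracy is exact: per variant, the
base value plus the sum of all feature attributions equals the model's
margin output.  The implementation is the polynomial-time path-dependent
algorithm for tree ensembles, run in float64 over the booster's dumped
trees (conditional expectations for absent features follow the training
cover fractions at each split).

Feature importance is the median absolute attribution per feature; a
signed-median mode exists for inspecting directionality, but absolute is
the default because signed medians cancel bidirectional effects and
break the ordering of features by absolute contribution.  Group
importance normalizes per-feature contributions to sum to one and
averages them within feature groups, splitting every tissue group into
modeled-tissue and other-tissue members (the differential- and
elevated-interaction subgroups are merged into a single interaction
group).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .data_model import FeatureMeta, FeatureTable, SchemaError
from .evaluation import bh_adjust, mannwhitney_one_tailed, wilcoxon_paired_one_tailed
from .training import TissueModel

# ---------------------------------------------------------------------------
# Tree parsing
# ---------------------------------------------------------------------------

_FEATURE_RE = re.compile(r"^f(\d+)$")


@dataclass
class _Tree:
    children_yes: np.ndarray
    children_no: np.ndarray
    children_missing: np.ndarray
    feature: np.ndarray  # -1 for leaves
    threshold: np.ndarray
    value: np.ndarray  # leaf values
    cover: np.ndarray


def _parse_tree(node_json: dict, n_features: int) -> _Tree:
    nodes: dict[int, dict] = {}

    def walk(nd):
        nodes[nd["nodeid"]] = nd
        for c in nd.get("children", ()):
            walk(c)

    walk(node_json)
    n = max(nodes) + 1
    t = _Tree(
        children_yes=np.full(n, -1, dtype=int),
        children_no=np.full(n, -1, dtype=int),
        children_missing=np.full(n, -1, dtype=int),
        feature=np.full(n, -1, dtype=int),
        threshold=np.zeros(n),
        value=np.zeros(n),
        cover=np.zeros(n),
    )
    for i, nd in nodes.items():
        t.cover[i] = nd["cover"]
        if "leaf" in nd:
            t.value[i] = nd["leaf"]
        else:
            m = _FEATURE_RE.match(nd["split"])
            t.feature[i] = int(m.group(1)) if m else -1
            if t.feature[i] >= n_features:
                raise SchemaError("tree split feature outside the model schema")
            # the booster compares float32 values; mirror that exactly
            t.threshold[i] = np.float32(nd["split_condition"])
            t.children_yes[i] = nd["yes"]
            t.children_no[i] = nd["no"]
            t.children_missing[i] = nd["missing"]
    return t


def _booster_trees(model: TissueModel, n_features: int) -> list[_Tree]:
    dump = model.booster().get_dump(dump_format="json", with_stats=True)
    return [_parse_tree(json.loads(d), n_features) for d in dump]


def _tree_route(t: _Tree, x: np.ndarray) -> float:
    node = 0
    while t.feature[node] >= 0:
        xf = np.float32(x[t.feature[node]])
        if np.isnan(xf):
            node = t.children_missing[node]
        elif xf < np.float32(t.threshold[node]):
            node = t.children_yes[node]
        else:
            node = t.children_no[node]
    return float(t.value[node])


def margin_scores(model: TissueModel, features: FeatureTable) -> np.ndarray:
    """Float64 margin (log-odds) output of the tree ensemble per variant.

    Sums the routed leaf values of every tree in float64; this is the
    exact margin of the ensemble, which the booster itself only reports
    after float32 accumulation.
    """
    if list(features.feature_names) != list(model.feature_schema):
        raise SchemaError("feature schema does not match the model")
    trees = _booster_trees(model, len(model.feature_schema))
    X = features.matrix()
    return np.array([sum(_tree_route(t, x) for t in trees) for x in X])


def _tree_expected_value(t: _Tree, node: int = 0) -> float:
    if t.feature[node] < 0:
        return float(t.value[node])
    yes, no = t.children_yes[node], t.children_no[node]
    wy = t.cover[yes] / t.cover[node]
    return wy * _tree_expected_value(t, yes) + (1 - wy) * _tree_expected_value(t, no)


# ---------------------------------------------------------------------------
# Path-dependent tree Shapley values
# ---------------------------------------------------------------------------
# Path elements are [feature, zero_fraction, one_fraction, pweight]; the
# recursion maintains the weighted count of feature subsets of each size
# along the current decision path.


def _extend(path: list[list], pz: float, po: float, pi: int) -> list[list]:
    path = [e[:] for e in path]
    path.append([pi, pz, po, 1.0 if len(path) == 0 else 0.0])
    ln = len(path) - 1
    for i in range(ln - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (ln + 1)
        path[i][3] = pz * path[i][3] * (ln - i) / (ln + 1)
    return path


def _unwind(path: list[list], i: int) -> list[list]:
    path = [e[:] for e in path]
    ln = len(path) - 1
    one, zero = path[i][2], path[i][1]
    n = path[ln][3]
    for j in range(ln - 1, -1, -1):
        if one != 0:
            tmp = path[j][3]
            path[j][3] = n * (ln + 1) / ((j + 1) * one)
            n = tmp - path[j][3] * zero * (ln - j) / (ln + 1)
        else:
            path[j][3] = path[j][3] * (ln + 1) / (zero * (ln - j))
    for j in range(i, ln):
        path[j][0], path[j][1], path[j][2] = path[j + 1][0], path[j + 1][1], path[j + 1][2]
    path.pop()
    return path


def _unwound_sum(path: list[list], i: int) -> float:
    ln = len(path) - 1
    one, zero = path[i][2], path[i][1]
    total = 0.0
    if one != 0:
        nxt = path[ln][3]
        for j in range(ln - 1, -1, -1):
            tmp = nxt * (ln + 1) / ((j + 1) * one)
            total += tmp
            nxt = path[j][3] - tmp * zero * (ln - j) / (ln + 1)
    else:
        for j in range(ln - 1, -1, -1):
            total += path[j][3] * (ln + 1) / (zero * (ln - j))
    return total


def _tree_shap(t: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(node: int, path: list[list], pz: float, po: float, pi: int) -> None:
        path = _extend(path, pz, po, pi)
        if t.feature[node] < 0:
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                el = path[i]
                phi[el[0]] += w * (el[2] - el[1]) * t.value[node]
            return
        f = t.feature[node]
        xf = np.float32(x[f])
        if np.isnan(xf):
            hot = t.children_missing[node]
        elif xf < np.float32(t.threshold[node]):
            hot = t.children_yes[node]
        else:
            hot = t.children_no[node]
        cold = t.children_no[node] if hot == t.children_yes[node] else t.children_yes[node]
        iz, io = 1.0, 1.0
        k = next((i for i in range(1, len(path)) if path[i][0] == f), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            path = _unwind(path, k)
        cov = t.cover[node]
        recurse(hot, path, iz * t.cover[hot] / cov, io, f)
        recurse(cold, path, iz * t.cover[cold] / cov, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------


@dataclass
class ShapExplanation:
    """Per-variant, per-feature attributions in margin (log-odds) space."""

    variant_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n_variants, n_features)
    base_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variant_ids, columns=self.feature_names)


def shap_explain(model: TissueModel, features: FeatureTable) -> ShapExplanation:
    """Exact tree-path Shapley attributions for every variant in ``features``.

    Local accuracy holds per variant: ``base_value + values.sum(1)``
    equals the booster's margin output to float64 precision.
    """
    if list(features.feature_names) != list(model.feature_schema):
        raise SchemaError("feature schema does not match the model")
    n_features = len(model.feature_schema)
    trees = _booster_trees(model, n_features)
    X = features.matrix()
    values = np.zeros((X.shape[0], n_features))
    for r in range(X.shape[0]):
        phi = np.zeros(n_features)
        for t in trees:
            if t.feature[0] < 0:  # constant stump contributes only to the base
                continue
            _tree_shap(t, X[r], phi)
        values[r] = phi
    base = sum(_tree_expected_value(t) for t in trees)  # logit(0.5) = 0 offset
    return ShapExplanation(list(features.variant_ids), list(model.feature_schema), values, float(base))


def feature_importance(expl: ShapExplanation, mode: str = "absolute") -> pd.Series:
    """Per-feature importance: median (absolute) attribution across variants."""
    if not expl.variant_ids:
        raise ValueError("explanation contains no variants")
    if mode == "absolute":
        vals = np.median(np.abs(expl.values), axis=0)
    elif mode == "signed":
        vals = np.median(expl.values, axis=0)
    else:
        raise ValueError("mode must be 'absolute' or 'signed'")
    return pd.Series(vals, index=expl.feature_names, name="importance")


def partition_features(
    meta: Sequence[FeatureMeta],
    modeled_tissue: str,
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[str]]:
    """Split the schema into variant-specific, modeled-tissue, and
    other-tissue feature sets.

    ``aliases`` maps each tissue to the tissue tags counted as "the
    modeled tissue" (the whole-brain model counts the brain subregions as
    its own).
    """
    aliases = dict(aliases if aliases is not None else schema.TISSUE_ALIASES)
    if modeled_tissue not in aliases:
        raise ValueError(f"unknown tissue {modeled_tissue!r}")
    mine = set(aliases[modeled_tissue])
    out = {"variant": [], "modeled_tissue": [], "other_tissue": []}
    for m in meta:
        if m.origin == "variant":
            out["variant"].append(m.name)
        elif m.tissue_tag in mine:
            out["modeled_tissue"].append(m.name)
        else:
            out["other_tissue"].append(m.name)
    return out


_MERGED_SUBGROUPS = {"differential_ppi": "ppi", "elevated_ppi": "ppi"}


@dataclass
class GroupImportance:
    """Mean normalized contribution per feature group.

    ``table`` rows: (group, partition) -> value; tissue groups appear
    twice, once for modeled-tissue members and once for the rest.
    ``normalized`` holds the per-feature normalized contributions (sum 1).
    """

    table: pd.DataFrame
    normalized: pd.Series


def group_importance(
    importances: pd.Series,
    meta: Sequence[FeatureMeta],
    modeled_tissue: str,
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> GroupImportance:
    total = float(importances.sum())
    if total <= 0:
        raise ValueError("total feature importance is zero; nothing to normalize")
    normalized = importances / total
    parts = partition_features(meta, modeled_tissue, aliases)
    modeled = set(parts["modeled_tissue"])
    rows = []
    groups: dict[tuple[str, str], list[float]] = {}
    for m in meta:
        if m.origin == "variant":
            key = (m.group, "variant")
        else:
            sub = _MERGED_SUBGROUPS.get(m.subgroup, m.subgroup)
            tag = "modeled_tissue" if m.name in modeled else "other_tissue"
            key = (sub, tag)
        groups.setdefault(key, []).append(float(normalized[m.name]))
    for (group, part), vals in groups.items():
        rows.append({"group": group, "partition": part, "value": float(np.mean(vals)), "n": len(vals)})
    table = pd.DataFrame(rows).sort_values("value", ascending=False, ignore_index=True)
    return GroupImportance(table, normalized)


def rank_feature_classes(
    importances: pd.Series, partition: Mapping[str, Sequence[str]]
) -> dict:
    """Rank all features by importance and test the modeled-tissue advantage.

    Rank 1 is the most important feature; ties take average ranks, and the
    ranking covers every feature (never a truncated top set).  One-tailed
    Mann-Whitney tests ask whether modeled-tissue features rank better
    (smaller) than variant-specific features and than other-tissue
    features; p-values are Benjamini-Hochberg adjusted.
    """
    for k in ("variant", "modeled_tissue", "other_tissue"):
        if not partition.get(k):
            raise ValueError(f"partition {k!r} is empty")
    ranks = pd.Series(
        stats.rankdata(-importances.to_numpy(), method="average"),
        index=importances.index,
        name="rank",
    )
    r = {k: ranks[list(v)].to_numpy() for k, v in partition.items()}
    p_vs_variant = mannwhitney_one_tailed(r["modeled_tissue"], r["variant"], "less")
    p_vs_other = mannwhitney_one_tailed(r["modeled_tissue"], r["other_tissue"], "less")
    adj = bh_adjust([p_vs_variant, p_vs_other])
    return {
        "ranks": ranks,
        "median_rank": {k: float(np.median(v)) for k, v in r.items()},
        "p_modeled_vs_variant": p_vs_variant,
        "p_modeled_vs_other": p_vs_other,
        "p_adj_modeled_vs_variant": float(adj[0]),
        "p_adj_modeled_vs_other": float(adj[1]),
    }


def rank_feature_classes_collective(median_ranks: pd.DataFrame) -> dict:
    """Cross-model comparison of per-model median ranks.

    ``median_ranks`` has one row per tissue model and columns
    ``variant``, ``modeled_tissue``, ``other_tissue``; one-tailed paired
    Wilcoxon tests ask whether modeled-tissue medians are smaller.
    """
    p_vs_variant = wilcoxon_paired_one_tailed(
        median_ranks["modeled_tissue"].to_numpy(), median_ranks["variant"].to_numpy(), "less"
    )
    p_vs_other = wilcoxon_paired_one_tailed(
        median_ranks["modeled_tissue"].to_numpy(), median_ranks["other_tissue"].to_numpy(), "less"
    )
    return {"p_modeled_vs_variant": p_vs_variant, "p_modeled_vs_other": p_vs_other}


def explain_variant(
    model: TissueModel,
    features: FeatureTable,
    variant_id: str,
    top_k: int = 20,
    meta: Sequence[FeatureMeta] | None = None,
) -> pd.DataFrame:
    """Top-k contributing features for one variant, by absolute attribution.

    Returns a frame ordered by decreasing |attribution| with the signed
    value and the feature's group and tissue tag.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    expl = shap_explain(model, features.subset([variant_id]))
    meta = list(meta if meta is not None else features.meta)
    meta_of = {m.name: m for m in meta}
    vals = pd.Series(expl.values[0], index=expl.feature_names)
    order = vals.abs().sort_values(ascending=False, kind="stable").index[:top_k]
    rows = [
        {
            "feature": f,
            "attribution": float(vals[f]),
            "group": meta_of[f].group if f in meta_of else "",
            "subgroup": meta_of[f].subgroup if f in meta_of else "",
            "tissue_tag": meta_of[f].tissue_tag if f in meta_of else None,
        }
        for f in order
    ]
    return pd.DataFrame(rows)
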