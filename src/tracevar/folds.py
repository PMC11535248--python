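"""Gene-disjoint, prevalence-preserving cross-validation folds.

Fold construction follows two constraints: all variants of a gene occupy
a single fold (preventing gene-level leakage between training and
validation), and every fold's pathogenic fraction stays close to the
tissue's overall pathogenic fraction.  Gene groups containing pathogenic
variants are assigned greedily (largest first, to the currently lightest
fold); benign-only gene groups are then drawn in seeded random order to
fill each fold's benign quota.  Benign variants left over are simply
unused for that tissue's cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import LabelMatrix


class FoldError(ValueError):
    """Fold construction is infeasible under the stated constraints."""


@dataclass
class FoldPlan:
    tissue: str
    folds: list[list[str]]  # variant ids per fold
    n_folds: int
    target_prevalence: float
    seed: int

    def to_json(self, path_or_buffer) -> None:
        payload = {
            "tissue": self.tissue,
            "n_folds": self.n_folds,
            "target_prevalence": self.target_prevalence,
            "seed": self.seed,
            "folds": self.folds,
        }
        if hasattr(path_or_buffer, "write"):
            json.dump(payload, path_or_buffer, indent=1)
        else:
            with open(path_or_buffer, "w") as fh:
                json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path_or_buffer) -> "FoldPlan":
        if hasattr(path_or_buffer, "read"):
            payload = json.load(path_or_buffer)
        else:
            with open(path_or_buffer) as fh:
                payload = json.load(fh)
        return cls(
            tissue=payload["tissue"],
            folds=[list(f) for f in payload["folds"]],
            n_folds=payload["n_folds"],
            target_prevalence=payload["target_prevalence"],
            seed=payload["seed"],
        )


@dataclass
class FoldValidationReport:
    gene_overlaps: list[str] = field(default_factory=list)
    missing_pathogenic: list[str] = field(default_factory=list)
    prevalence_violations: list[tuple[int, float]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.gene_overlaps or self.missing_pathogenic or self.prevalence_violations)


def auto_fold_count(
    n_pathogenic_genes: int, min_genes_per_fold: int = 4, max_folds: int = 15
) -> int:
    """Transparent fold-count rule: ``min(max_folds, max(2, n_genes // min_genes_per_fold))``.

    Calibrated so the observed extremes (2 folds for sparse tissues, 15
    for the largest) are reachable.
    """
    if n_pathogenic_genes < min_genes_per_fold:
        raise FoldError(
            f"only {n_pathogenic_genes} pathogenic genes (< {min_genes_per_fold}); "
            "pass an explicit n_folds or the override flag"
        )
    return min(max_folds, max(2, n_pathogenic_genes // min_genes_per_fold))


def plan_folds(
    labels: LabelMatrix,
    tissue: str,
    gene_of: Mapping[str, str],
    n_folds: int | None = None,
    tolerance: float = 0.1,
    seed: int = 0,
    min_pathogenic_genes: int = 20,
    allow_sparse: bool = False,
) -> FoldPlan:
    """Construct a validated fold plan for one tissue.

    ``gene_of`` maps variant id to gene symbol.  ``n_folds=None`` applies
    :func:`auto_fold_count`.  Tissues with pathogenic variants in fewer
    than ``min_pathogenic_genes`` genes are rejected unless
    ``allow_sparse`` is set.
    """
    y = labels.column(tissue)
    ids = labels.variant_ids
    path_ids = [v for v, lab in zip(ids, y) if lab == 1]
    if not path_ids:
        raise FoldError(f"tissue {tissue!r} has no pathogenic variants")

    path_set = set(path_ids)
    gene_groups: dict[str, list[str]] = {}
    for v in ids:
        gene_groups.setdefault(gene_of[v], []).append(v)
    path_count = {g: sum(1 for v in vs if v in path_set) for g, vs in gene_groups.items()}
    path_genes = [g for g, c in path_count.items() if c > 0]
    if len(path_genes) < min_pathogenic_genes and not allow_sparse:
        raise FoldError(
            f"tissue {tissue!r} has pathogenic variants in only {len(path_genes)} genes "
            f"(< {min_pathogenic_genes}); set allow_sparse to proceed"
        )
    if n_folds is None:
        n_folds = auto_fold_count(len(path_genes))
    if n_folds > len(path_genes):
        raise FoldError(
            f"n_folds={n_folds} exceeds the number of genes with pathogenic variants "
            f"({len(path_genes)}); the gene-disjointness constraint is binding"
        )
    if n_folds < 2:
        raise FoldError("n_folds must be >= 2")

    target = len(path_ids) / len(ids)
    rng = np.random.default_rng(seed)

    # pathogenic gene groups: largest first, to the fold lightest in positives
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    fold_pos = np.zeros(n_folds, dtype=int)
    fold_ben = np.zeros(n_folds, dtype=int)
    for g in sorted(path_genes, key=lambda g: (-path_count[g], g)):
        f = int(np.argmin(fold_pos + 1e-9 * fold_ben))
        folds[f].extend(gene_groups[g])
        fold_pos[f] += path_count[g]
        fold_ben[f] += len(gene_groups[g]) - path_count[g]

    # benign-only gene groups, drawn in seeded random order, balance the
    # per-fold pathogenic fraction: each group joins the currently most
    # undersupplied fold (highest pathogenic fraction), capped so no fold
    # leaves the tolerance window around the target prevalence
    benign_genes = [g for g in gene_groups if path_count[g] == 0]
    rng.shuffle(benign_genes)
    benign_genes.sort(key=lambda g: -len(gene_groups[g]))  # big first; seeded tie order
    ben_max = np.floor(fold_pos * (1.0 / (target * (1.0 - tolerance)) - 1.0) + 1e-9).astype(int)
    ben_min = np.ceil(fold_pos * (1.0 / (target * (1.0 + tolerance)) - 1.0) - 1e-9).astype(int)
    if np.any(fold_ben > ben_max):
        raise FoldError(
            "benign variants sharing genes with pathogenic variants already exceed "
            "the per-fold prevalence tolerance; fewer folds may help"
        )
    placed: list[list[str]] = [[] for _ in range(n_folds)]  # benign-only genes per fold
    for g in benign_genes:
        size = len(gene_groups[g])
        prev = fold_pos / np.maximum(fold_pos + fold_ben, 1)
        for f in np.argsort(-prev):
            if fold_ben[f] + size <= ben_max[f]:
                placed[int(f)].append(g)
                fold_ben[f] += size
                break
        # a group fitting no fold stays unused for this tissue's CV

    # repair pass: a fold still under its benign minimum pulls a suitably
    # sized group from a donor fold that can spare it
    for _ in range(4 * n_folds):
        starved = [f for f in range(n_folds) if fold_ben[f] < ben_min[f]]
        if not starved:
            break
        f = starved[0]
        moved = False
        for donor in sorted(range(n_folds), key=lambda d: ben_min[d] - fold_ben[d]):
            if donor == f:
                continue
            for g in sorted(placed[donor], key=lambda g: len(gene_groups[g])):
                size = len(gene_groups[g])
                if fold_ben[donor] - size >= ben_min[donor] and fold_ben[f] + size <= ben_max[f]:
                    placed[donor].remove(g)
                    placed[f].append(g)
                    fold_ben[donor] -= size
                    fold_ben[f] += size
                    moved = True
                    break
            if moved:
                break
        if not moved:
            break
    for f in range(n_folds):
        for g in placed[f]:
            folds[f].extend(gene_groups[g])

    plan = FoldPlan(
        tissue=tissue,
        folds=folds,
        n_folds=n_folds,
        target_prevalence=target,
        seed=seed,
    )
    report = validate_fold_plan(plan, gene_of, labels=labels, tolerance=tolerance)
    if not report.ok:
        raise FoldError(f"constructed plan failed validation: {report}")
    return plan


def validate_fold_plan(
    plan: FoldPlan,
    gene_of: Mapping[str, str],
    labels: LabelMatrix | None = None,
    tolerance: float = 0.1,
) -> FoldValidationReport:
    """Check gene-disjointness, pathogenic coverage, and per-fold prevalence.

    An empty report means the plan is valid.  Coverage and prevalence are
    only checked when ``labels`` is supplied.
    """
    report = FoldValidationReport()
    gene_fold: dict[str, int] = {}
    for f, fold in enumerate(plan.folds):
        for v in fold:
            g = gene_of[v]
            if g in gene_fold and gene_fold[g] != f:
                if g not in report.gene_overlaps:
                    report.gene_overlaps.append(g)
            gene_fold[g] = f
    if labels is not None:
        y = dict(zip(labels.variant_ids, labels.column(plan.tissue)))
        assigned = {v for fold in plan.folds for v in fold}
        report.missing_pathogenic = [v for v, lab in y.items() if lab == 1 and v not in assigned]
        for f, fold in enumerate(plan.folds):
            n_pos = sum(int(y[v]) for v in fold)
            if not fold or n_pos == 0:
                report.prevalence_violations.append((f, 0.0))
                continue
            prev = n_pos / len(fold)
            if abs(prev - plan.target_prevalence) > tolerance * plan.target_prevalence:
                report.prevalence_violations.append((f, prev))
    return report
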