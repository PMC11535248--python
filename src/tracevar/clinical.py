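"""Patient-level candidate filtering, prioritization, and cohort summaries.

Candidate variants of a diagnosed patient pass a filtration cascade —
rare in population databases (allele frequency below 0.5%), predicted
possibly deleterious (loss-of-function, missense or splice-altering
consequence, or CADD score above 15), zygosity consistent with the
presumed mode of inheritance, and upstream read-quality/region flags —
and are then ranked by the pathogenicity score of the model of the
patient's affected tissue.  The rank of the verified pathogenic variant,
expressed as a percentile of the candidate list, is the per-case outcome;
cohort summaries report the fractions of cases ranking above the median,
in the top quartile, and in the top decile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import FeatureTable, LabelMatrix, VariantKey
from .training import TissueModel, fit_tissue_model, predict_scores

DELETERIOUS_CONSEQUENCES = frozenset({"LoF", "missense", "splice-altering"})

#: Allowed zygosities per mode of inheritance.
DEFAULT_ZYGOSITY_TABLE: dict[str, frozenset[str]] = {
    "recessive": frozenset({"homozygous", "compound-heterozygous"}),
    "dominant": frozenset({"heterozygous", "homozygous", "hemizygous", "compound-heterozygous"}),
    "x-linked-dominant": frozenset({"heterozygous", "homozygous", "hemizygous"}),
    "x-linked-recessive": frozenset({"hemizygous", "homozygous"}),
}


@dataclass(frozen=True)
class CandidateVariant:
    key: VariantKey
    max_population_af: float
    consequence_class: str  # LoF | missense | splice-altering | other
    cadd_score: float
    zygosity: str
    passes_quality: bool = True
    passes_region: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_population_af <= 1.0:
            raise ValueError("max_population_af must lie in [0, 1]")


@dataclass
class PatientCase:
    case_id: str
    affected_tissues: list[str]
    candidates: list[CandidateVariant]
    verified: list[VariantKey]
    mode_of_inheritance: str = "recessive"

    def __post_init__(self) -> None:
        if not 1 <= len(self.affected_tissues) <= 2:
            raise ValueError("a case has one or two affected tissues")
        cand_keys = {c.key for c in self.candidates}
        if not set(self.verified) <= cand_keys:
            raise ValueError("verified variants must be among the candidates")


def filter_candidates(
    candidates: Sequence[CandidateVariant],
    af_cutoff: float = 0.005,
    cadd_cutoff: float = 15.0,
    zygosity_table: Mapping[str, frozenset[str]] | None = None,
    mode_of_inheritance: str = "recessive",
) -> list[CandidateVariant]:
    """Apply the filtration cascade; criteria are order-independent.

    Keeps candidates that pass the upstream quality and region flags, are
    rare (allele frequency strictly below ``af_cutoff``; a frequency equal
    to the cutoff is excluded), look possibly deleterious (deleterious
    consequence class or CADD score strictly above ``cadd_cutoff``), and
    carry a zygosity allowed under the mode of inheritance.
    """
    table = dict(zygosity_table if zygosity_table is not None else DEFAULT_ZYGOSITY_TABLE)
    if mode_of_inheritance not in table:
        raise ValueError(f"unknown mode of inheritance {mode_of_inheritance!r}")
    allowed = table[mode_of_inheritance]
    kept = []
    for c in candidates:
        if not (c.passes_quality and c.passes_region):
            continue
        if c.max_population_af >= af_cutoff:
            continue
        if c.consequence_class not in DELETERIOUS_CONSEQUENCES and c.cadd_score <= cadd_cutoff:
            continue
        if c.zygosity not in allowed:
            continue
        kept.append(c)
    return kept


def case_specific_training_set(
    all_ids: Sequence[str], gene_of: Mapping[str, str], candidate_genes: Sequence[str]
) -> list[str]:
    """Training ids excluding every variant in a candidate gene (leakage guard)."""
    if not candidate_genes:
        raise ValueError("candidate gene list is empty")
    banned = set(candidate_genes)
    return [v for v in all_ids if gene_of[v] not in banned]


@dataclass
class RankedCandidates:
    tissue: str
    table: pd.DataFrame  # columns: variant_id, score, rank (average ties)


def prioritize_case(
    case: PatientCase,
    features: FeatureTable,
    label_matrix: LabelMatrix,
    candidate_features: FeatureTable,
    mode: str = "full",
    seed: int = 0,
    hyperparams: Mapping | None = None,
    models: Mapping[str, TissueModel] | None = None,
) -> dict[str, RankedCandidates]:
    """Rank the case's candidate variants per affected tissue.

    ``mode='full'`` trains on the whole labeled dataset;
    ``mode='case_specific'`` removes variants sharing a gene with any
    candidate.  Pre-fitted ``models`` (keyed by tissue) short-circuit
    training and are only valid in full mode.  Candidates are ranked by
    descending pathogenicity score with average ranks on ties.
    """
    if mode not in ("full", "case_specific"):
        raise ValueError("mode must be 'full' or 'case_specific'")
    gene_of = {v.id: v.gene for v in features.variants}
    cand_genes = sorted({c.key.gene for c in case.candidates})
    cand_ids = [c.key.id for c in case.candidates]
    sub_cand = candidate_features.subset(cand_ids)
    row = {vid: i for i, vid in enumerate(label_matrix.variant_ids)}

    out: dict[str, RankedCandidates] = {}
    for tissue in case.affected_tissues:
        if models is not None and mode == "full" and tissue in models:
            model = models[tissue]
        else:
            if mode == "full":
                train_ids = list(features.variant_ids)
            else:
                train_ids = case_specific_training_set(features.variant_ids, gene_of, cand_genes)
            train = features.subset(train_ids)
            y = label_matrix.column(tissue)[[row[v] for v in train_ids]]
            if y.min() == y.max():
                raise ValueError(
                    f"tissue {tissue!r} is untrainable: single-class training labels"
                )
            model = fit_tissue_model(train, y, tissue, hyperparams, seed)
        scores = predict_scores(model, sub_cand).scores
        ranks = stats.rankdata(-scores, method="average")
        table = pd.DataFrame(
            {"variant_id": sub_cand.variant_ids, "score": scores, "rank": ranks}
        ).sort_values("rank", ignore_index=True)
        out[tissue] = RankedCandidates(tissue, table)
    return out


def rank_of_verified(ranked: RankedCandidates, verified: VariantKey) -> tuple[float, float]:
    """(rank, percentile) of the verified variant; average-rank tie handling."""
    t = ranked.table
    hit = t[t["variant_id"] == verified.id]
    if hit.empty:
        raise ValueError(f"verified variant {verified.id} absent from the ranked list")
    rank = float(hit["rank"].iloc[0])
    return rank, rank / len(t)


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    n_above_median: int
    n_top_quartile: int
    n_top_decile: int
    frac_above_median: float
    frac_top_quartile: float
    frac_top_decile: float


def summarize_cases(percentiles: Sequence[float]) -> CohortSummary:
    """Cohort fractions: percentile < 0.5 (above median, strict), <= 0.25, <= 0.10."""
    p = np.asarray(percentiles, dtype=float)
    if p.size == 0:
        raise ValueError("no case percentiles supplied")
    n = p.size
    nm = int((p < 0.5).sum())
    nq = int((p <= 0.25).sum())
    nd = int((p <= 0.10).sum())
    return CohortSummary(n, nm, nq, nd, nm / n, nq / n, nd / n)
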