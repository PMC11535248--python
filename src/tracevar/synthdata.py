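"""Synthetic generator for tissue-aware variant pathogenicity data.

Emulates the joint structure of the real inputs — clinical variant
records, a disease-to-tissue map, per-variant annotation features, and
per-gene tissue features — with controllable tissue-conditional signal,
so every downstream module is testable without external downloads.

Generative model
----------------
Genes carry baseline tissue profiles (standard normal per tissue
feature).  Per tissue, a disjoint set of genes is designated pathogenic
in that tissue: its features tagged with the tissue (and its aliases) are
shifted additively by the per-subgroup ``tissue_effect``, emulating
preferential expression and activity of disease genes in their affected
tissue.  A fraction of those genes' variants is labeled pathogenic; such
variants draw their pathogenicity-score features from a Beta distribution
shifted by ``variant_effect`` and their molecular consequence from a
deleterious-leaning categorical, while benign variants use neutral
distributions.  Under ``interaction=True``, single-signal decoys are
added and labeled benign — variants with deleterious-looking annotation
in unremarkable genes, and genes with a tissue-shifted profile but only
benign variants — so that pathogenicity requires BOTH signals, a regime a
post hoc score average cannot represent.

A ``missing_rate`` fraction of raw feature cells is blanked before
assembly, exercising the imputation path.  Per-tissue pathogenic
prevalence defaults to 1.7%, the median per-tissue rate of a curated
clinical-variant dataset of this kind.  All draws flow from a single
seeded generator: identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema
from .clinical import CandidateVariant, PatientCase
from .data_model import (
    ClinRecord,
    DiseaseTissueMap,
    FeatureMeta,
    FeatureTable,
    LabelMatrix,
    VariantKey,
    assemble_features,
    build_label_matrix,
)

_BENIGN_CONSEQ_P = {
    "synonymous": 0.35, "intronic": 0.25, "utr_3": 0.10, "utr_5": 0.08,
    "missense": 0.12, "upstream": 0.05, "splice_region": 0.05,
}
_PATHO_CONSEQ_P = {
    "missense": 0.45, "stop_gained": 0.15, "frameshift": 0.15,
    "splice_donor": 0.08, "splice_acceptor": 0.07, "start_lost": 0.05,
    "inframe_deletion": 0.05,
}

_SCORE_ALPHA, _SCORE_BETA = 2.0, 8.0
_SCORE_SHIFT_PER_EFFECT = 4.0  # added to alpha per unit of variant_effect


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator."""

    n_genes: int = 400
    n_variants: int = 5000
    tissues: tuple[str, ...] = schema.TISSUES
    prevalence: float = 0.017
    tissue_effect: float | Mapping[str, float] = 1.5
    variant_effect: float = 1.0
    missing_rate: float = 0.05
    interaction: bool = False
    pathogenic_fraction_within_gene: float = 0.6
    year_range: tuple[int, int] = (2016, 2024)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        unknown = set(self.tissues) - set(schema.TISSUES)
        if unknown:
            raise ValueError(f"tissues outside the vocabulary: {sorted(unknown)}")

    def effect_of(self, subgroup: str) -> float:
        if isinstance(self.tissue_effect, Mapping):
            return float(self.tissue_effect.get(subgroup, 0.0))
        return float(self.tissue_effect)


@dataclass
class SimulatedData:
    """A complete synthetic study: features (pre-imputation), labels, provenance."""

    features: FeatureTable
    labels: LabelMatrix
    gene_of: dict[str, str]
    records: list[ClinRecord]
    dmap: DiseaseTissueMap
    meta: list[FeatureMeta]
    pathogenic_genes: dict[str, list[str]]  # tissue -> designated genes


def _draw_consequences(rng: np.random.Generator, n: int, probs: Mapping[str, float]) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[l] for l in levels])
    return rng.choice(levels, size=n, p=p / p.sum())


def _score_features(rng: np.random.Generator, n: int, effect: float) -> np.ndarray:
    a = _SCORE_ALPHA + _SCORE_SHIFT_PER_EFFECT * max(effect, 0.0)
    return rng.beta(a, _SCORE_BETA, size=n)


def _gene_feature_frame(rng: np.random.Generator, genes: Sequence[str], meta: Sequence[FeatureMeta]) -> pd.DataFrame:
    cols = [m.name for m in meta if m.origin == "tissue"]
    return pd.DataFrame(
        rng.normal(size=(len(genes), len(cols))), index=pd.Index(genes, name="gene"), columns=cols
    )


def _apply_tissue_shift(
    gene_features: pd.DataFrame,
    genes: Sequence[str],
    tissue: str,
    config: SimConfig,
    meta: Sequence[FeatureMeta],
) -> None:
    aliases = set(schema.TISSUE_ALIASES.get(tissue, (tissue,)))
    for m in meta:
        if m.origin != "tissue" or m.tissue_tag not in aliases:
            continue
        eff = config.effect_of(m.subgroup)
        if eff:
            gene_features.loc[list(genes), m.name] += eff


def _variant_feature_frame(
    rng: np.random.Generator,
    keys: Sequence[VariantKey],
    is_pathogenic: np.ndarray,
    variant_effect: float,
    meta: Sequence[FeatureMeta],
    deleterious_like: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw (pre-one-hot) per-variant annotation table.

    ``deleterious_like`` marks additional benign variants whose annotation
    profile mimics pathogenic ones (interaction decoys).
    """
    n = len(keys)
    shifted = is_pathogenic.copy()
    if deleterious_like is not None:
        shifted = shifted | deleterious_like
    df = pd.DataFrame(index=pd.Index([k.id for k in keys]))
    numeric = [m for m in meta if m.origin == "variant" and m.dtype == "numeric"]
    for m in numeric:
        if m.group == "pathogenic_score":
            vals = np.where(
                shifted,
                _score_features(rng, n, variant_effect),
                _score_features(rng, n, 0.0),
            )
        elif m.group == "allele_frequency":
            vals = rng.beta(0.5, 30.0, size=n)
        else:
            vals = rng.normal(size=n)
        df[m.name] = vals
    # consequence shift scales with the variant effect: at zero effect the
    # deleterious-leaning distribution collapses onto the benign one
    w = min(1.0, max(0.0, variant_effect))
    levels = sorted(set(_BENIGN_CONSEQ_P) | set(_PATHO_CONSEQ_P))
    pb = np.array([_BENIGN_CONSEQ_P.get(l, 0.0) for l in levels])
    pp = np.array([_PATHO_CONSEQ_P.get(l, 0.0) for l in levels])
    mix = {l: v for l, v in zip(levels, (1 - w) * pb / pb.sum() + w * pp / pp.sum())}
    conseq = np.where(
        shifted,
        _draw_consequences(rng, n, mix),
        _draw_consequences(rng, n, _BENIGN_CONSEQ_P),
    )
    df["consequence"] = conseq
    return df


def _mask_cells(rng: np.random.Generator, df: pd.DataFrame, rate: float, skip: Sequence[str] = ()) -> None:
    if rate <= 0:
        return
    cols = [c for c in df.columns if c not in set(skip)]
    mask = rng.random(size=(len(df), len(cols))) < rate
    vals = df[cols].to_numpy(dtype=object)
    vals[mask] = np.nan
    df[cols] = vals


def generate_dataset(config: SimConfig) -> SimulatedData:
    """Generate a full synthetic labeled dataset under ``config``."""
    rng = np.random.default_rng(config.seed)
    meta = schema.default_feature_meta(config.tissues)

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    gene_idx = rng.integers(0, config.n_genes, size=config.n_variants)
    bases = np.array(list("ACGT"))
    keys = []
    for i in range(config.n_variants):
        ref, alt = rng.choice(4, size=2, replace=False)
        keys.append(VariantKey("1", i + 1, bases[ref], bases[alt], genes[gene_idx[i]]))
    gene_of = {k.id: k.gene for k in keys}
    variants_of: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        variants_of.setdefault(k.gene, []).append(i)

    # designate disjoint pathogenic gene sets per tissue until each tissue
    # reaches its pathogenic-variant target
    n_target = int(round(config.prevalence * config.n_variants))
    if n_target < 1:
        raise ValueError("prevalence infeasible for n_variants: no pathogenic variants")
    pool = [g for g in genes if g in variants_of]
    rng.shuffle(pool)
    pathogenic_genes: dict[str, list[str]] = {t: [] for t in config.tissues}
    patho_tissue_of_variant: dict[int, str] = {}
    cursor = 0
    for t in config.tissues:
        count = 0
        while count < n_target:
            if cursor >= len(pool):
                raise ValueError(
                    f"prevalence {config.prevalence} infeasible: gene pool exhausted at tissue {t!r}"
                )
            g = pool[cursor]
            cursor += 1
            pathogenic_genes[t].append(g)
            vs = variants_of[g]
            k = max(1, int(round(config.pathogenic_fraction_within_gene * len(vs))))
            chosen = rng.choice(len(vs), size=min(k, len(vs)), replace=False)
            for j in chosen:
                patho_tissue_of_variant[vs[j]] = t
                count += 1

    is_path = np.zeros(config.n_variants, dtype=bool)
    is_path[list(patho_tissue_of_variant)] = True

    # interaction decoys: deleterious-looking benign variants in plain genes,
    # and tissue-shifted genes with only benign variants
    deleterious_like = np.zeros(config.n_variants, dtype=bool)
    decoy_genes: dict[str, list[str]] = {t: [] for t in config.tissues}
    if config.interaction:
        # tissue-signal-only decoys: benign genes given the tissue shift
        for t in config.tissues:
            take = pool[cursor : cursor + max(2, len(pathogenic_genes[t]) // 2)]
            decoy_genes[t] = list(take)
            cursor += len(take)
        # variant-signal-only decoys: deleterious-looking benign variants in
        # genes carrying neither pathogenic variants nor a tissue shift
        shifted_genes = {g for gs in decoy_genes.values() for g in gs}
        plain = [
            i
            for i in range(config.n_variants)
            if not is_path[i] and keys[i].gene not in shifted_genes
            and keys[i].gene not in {g for gs in pathogenic_genes.values() for g in gs}
        ]
        n_decoy = min(len(plain), n_target * len(config.tissues))
        if n_decoy:
            chosen = rng.choice(len(plain), size=n_decoy, replace=False)
            deleterious_like[[plain[j] for j in chosen]] = True

    # feature tables
    gene_features = _gene_feature_frame(rng, genes, meta)
    for t in config.tissues:
        _apply_tissue_shift(gene_features, pathogenic_genes[t], t, config, meta)
        if decoy_genes[t]:
            _apply_tissue_shift(gene_features, decoy_genes[t], t, config, meta)
    variant_features = _variant_feature_frame(
        rng, keys, is_path, config.variant_effect, meta, deleterious_like
    )

    _mask_cells(rng, variant_features, config.missing_rate, skip=("consequence",))
    _mask_cells(rng, gene_features, config.missing_rate)

    # clinical records and the disease->tissue map
    omim_of_gene = {
        g: f"6{schema.TISSUES.index(t):02d}{i:03d}"
        for t, gs in pathogenic_genes.items()
        for i, g in enumerate(gs)
    }
    tissue_of_omim = {
        omim_of_gene[g]: t for t, gs in pathogenic_genes.items() for g in gs
    }
    dmap = DiseaseTissueMap(
        tissues_of={o: frozenset({t}) for o, t in tissue_of_omim.items()},
        molecular_basis=frozenset(tissue_of_omim),
        vocabulary=tuple(config.tissues),
    )
    y_lo, y_hi = config.year_range
    years = rng.integers(y_lo, y_hi + 1, size=config.n_variants)
    stars = rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1], size=config.n_variants)
    records = []
    for i, k in enumerate(keys):
        if is_path[i]:
            records.append(
                ClinRecord(k, int(stars[i]), 1, (omim_of_gene[k.gene],), int(years[i]))
            )
        else:
            records.append(ClinRecord(k, int(stars[i]), 0, (), int(years[i])))

    labels = build_label_matrix(records, dmap, config.tissues)
    features = assemble_features(
        variant_features, gene_features, meta, [r.key for r in records],
        categorical_vocabs=schema.CATEGORICAL_VOCABS,
    )
    return SimulatedData(
        features=features,
        labels=labels,
        gene_of=gene_of,
        records=records,
        dmap=dmap,
        meta=meta,
        pathogenic_genes=pathogenic_genes,
    )


def generate_patient_case(
    config: SimConfig,
    n_candidates: int,
    affected_tissue: str,
    seed: int,
    case_id: str = "case",
) -> tuple[PatientCase, FeatureTable]:
    """A synthetic diagnosed patient: post-filtration candidates plus features.

    ``n_candidates - 1`` background variants are drawn from the benign
    generative distribution in the post-filtration regime (rare alleles,
    deleterious-looking consequence or CADD above 15), and one planted
    variant carries both the variant-level and the affected-tissue signal;
    the planted variant is the case's verified pathogenic variant.
    """
    if n_candidates < 2:
        raise ValueError("a case needs at least 2 candidates")
    rng = np.random.default_rng(seed)
    meta = schema.default_feature_meta(config.tissues)
    n = n_candidates
    genes = [f"P{seed % 100000}_{i:04d}" for i in range(n)]  # one gene per candidate
    keys = [VariantKey("2", i + 1, "A", "G", genes[i]) for i in range(n)]
    planted = rng.integers(0, n)

    is_planted = np.zeros(n, dtype=bool)
    is_planted[planted] = True
    variant_features = _variant_feature_frame(rng, keys, is_planted, config.variant_effect, meta)
    gene_features = _gene_feature_frame(rng, genes, meta)
    _apply_tissue_shift(gene_features, [genes[planted]], affected_tissue, config, meta)
    _mask_cells(rng, variant_features, config.missing_rate, skip=("consequence",))
    _mask_cells(rng, gene_features, config.missing_rate)

    candidates = []
    for i, k in enumerate(keys):
        deleterious = bool(rng.random() < 0.7) or i == planted
        candidates.append(
            CandidateVariant(
                key=k,
                max_population_af=float(rng.uniform(0.0, 0.004)),
                consequence_class="missense" if deleterious else "other",
                cadd_score=float(rng.uniform(16.0, 35.0)) if not deleterious else float(rng.uniform(5.0, 35.0)),
                zygosity="homozygous",
            )
        )
    case = PatientCase(
        case_id=case_id,
        affected_tissues=[affected_tissue],
        candidates=candidates,
        verified=[keys[planted]],
        mode_of_inheritance="recessive",
    )
    features = assemble_features(
        variant_features, gene_features, meta, keys,
        categorical_vocabs=schema.CATEGORICAL_VOCABS,
    )
    return case, features


def generate_leave_gene_out_scenario(
    config: SimConfig,
    gene_tissue: str,
    n_pathogenic: int = 8,
    n_benign: int = 10,
) -> tuple[SimulatedData, str]:
    """Embed a designated mixed-label gene in a background dataset.

    The designated gene carries ``n_pathogenic`` variants pathogenic only
    in ``gene_tissue`` (variant- and tissue-level signal) alongside
    ``n_benign`` benign variants, mirroring a gene whose variants cause a
    single-tissue disease.
    """
    if len(config.tissues) < 6:
        raise ValueError("the scenario needs at least 6 tissues for contrast")
    if gene_tissue not in config.tissues:
        raise ValueError(f"{gene_tissue!r} not among the configured tissues")
    base = generate_dataset(config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    meta = base.meta
    gene = "LGO_GENE"
    n = n_pathogenic + n_benign
    keys = [VariantKey("3", i + 1, "C", "T", gene) for i in range(n)]
    is_path = np.arange(n) < n_pathogenic

    vf = _variant_feature_frame(rng, keys, is_path, config.variant_effect, meta)
    gf = _gene_feature_frame(rng, [gene], meta)
    _apply_tissue_shift(gf, [gene], gene_tissue, config, meta)

    omim = "699999"
    dmap = DiseaseTissueMap(
        tissues_of={**{k: v for k, v in base.dmap.tissues_of.items()}, omim: frozenset({gene_tissue})},
        molecular_basis=base.dmap.molecular_basis | {omim},
        vocabulary=base.dmap.vocabulary,
    )
    records = list(base.records)
    for i, k in enumerate(keys):
        if is_path[i]:
            records.append(ClinRecord(k, 2, 1, (omim,), 2020))
        else:
            records.append(ClinRecord(k, 2, 0, (), 2020))

    extra_features = assemble_features(
        vf, gf, meta, keys, categorical_vocabs=schema.CATEGORICAL_VOCABS
    )
    features = FeatureTable(
        base.features.variants + keys,
        meta,
        pd.concat([base.features.values, extra_features.values]),
    )
    labels = build_label_matrix(records, dmap, config.tissues)
    gene_of = dict(base.gene_of, **{k.id: gene for k in keys})
    return (
        SimulatedData(features, labels, gene_of, records, dmap, meta, base.pathogenic_genes),
        gene,
    )
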