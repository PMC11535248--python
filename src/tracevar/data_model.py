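"""Variant records, tissue-aware labels, and the combined feature table.

This module turns ClinVar-style variant annotation rows and a
disease-to-affected-tissue map into a binary variants x tissues label
matrix, and joins per-variant annotation features with per-gene tissue
features into a single numeric table ready for model fitting.

Labeling logic
--------------
A variant is labeled *pathogenic in tissue t* when (i) its record is
reliable (review stars >= 2), (ii) it is linked to at least one disease
with a known molecular basis (OMIM phenotype mapping key 3), and
(iii) that disease clinically manifests in tissue t.  Variants with a
benign clinical-significance flag and no disease link are labeled
*benign in every tissue*.  Records satisfying neither rule are excluded.

Feature assembly
----------------
Each variant row is the concatenation of its variant-specific feature
values and the tissue-specific feature values of its gene.  Categorical
variant columns (e.g. the molecular consequence) are expanded into
indicator columns over a frozen vocabulary.  Missing values are filled
with per-feature defaults for variant-specific columns and with zero for
tissue-specific columns.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOME_BUILDS = ("GRCh37", "GRCh38")


class SchemaError(ValueError):
    """A table or metadata list violates the expected schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a genetic variant: (chrom, pos, ref, alt, build) plus gene.

    Alleles are taken as given; upstream annotation tables are assumed
    pre-normalized (no left-alignment is attempted here).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.build not in GENOME_BUILDS:
            raise ValueError(f"unknown genome build {self.build!r}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}:{self.build}"


@dataclass(frozen=True)
class ClinRecord:
    """A reliability-annotated clinical variant record."""

    key: VariantKey
    stars: int
    clin_sig_simple: int
    phenotype_omim_ids: tuple[str, ...] = ()
    annotation_year: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.stars <= 4:
            raise ValueError(f"review stars must lie in [0, 4], got {self.stars}")
        if self.annotation_year and self.annotation_year < 1990:
            raise ValueError(f"implausible annotation year {self.annotation_year}")


@dataclass(frozen=True)
class DiseaseTissueMap:
    """Mapping from OMIM phenotype id to the disease's affected tissues.

    ``molecular_basis`` holds the ids whose disease has a known molecular
    basis (OMIM phenotype mapping key 3); only those ids can make a
    variant pathogenic.
    """

    tissues_of: Mapping[str, frozenset[str]]
    molecular_basis: frozenset[str]
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        for omim, tset in self.tissues_of.items():
            unknown = tset - vocab
            if unknown:
                raise ValueError(
                    f"OMIM {omim} maps to tissues outside the vocabulary: {sorted(unknown)}"
                )

    @classmethod
    def from_tsv(cls, path_or_buffer, vocabulary: Sequence[str]) -> "DiseaseTissueMap":
        """Read a (omim_id, tissue[, mapping_key]) TSV.

        Rows with mapping_key != 3 contribute the id but not molecular-basis
        status; the mapping_key column defaults to 3 when absent.
        """
        df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
        required = {"omim_id", "tissue"}
        if not required.issubset(df.columns):
            raise SchemaError(f"tissue map requires columns {sorted(required)}")
        keys = df["mapping_key"].astype(int) if "mapping_key" in df.columns else pd.Series(3, index=df.index)
        tissues_of: dict[str, set[str]] = {}
        basis: set[str] = set()
        for (omim, tissue), mk in zip(df[["omim_id", "tissue"]].itertuples(index=False), keys):
            tissues_of.setdefault(omim, set()).add(tissue)
            if mk == 3:
                basis.add(omim)
        return cls(
            tissues_of={k: frozenset(v) for k, v in tissues_of.items()},
            molecular_basis=frozenset(basis),
            vocabulary=tuple(vocabulary),
        )


@dataclass
class LabelMatrix:
    """Binary variants x tissues pathogenicity labels."""

    variants: list[VariantKey]
    tissues: list[str]
    labels: np.ndarray  # shape (n_variants, n_tissues), int8
    is_benign_everywhere: np.ndarray  # shape (n_variants,), bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.is_benign_everywhere = np.asarray(self.is_benign_everywhere, dtype=bool)
        n, t = self.labels.shape
        if n != len(self.variants) or t != len(self.tissues):
            raise ValueError("label matrix dimensions do not match key/tissue lists")
        row_any = self.labels.any(axis=1)
        if np.any(self.is_benign_everywhere & row_any):
            raise ValueError("benign-everywhere variant with a nonzero label row")
        if np.any(~self.is_benign_everywhere & ~row_any):
            raise ValueError("pathogenic variant with an all-zero label row")

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, tissue: str) -> np.ndarray:
        return self.labels[:, self.tissues.index(tissue)]

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "build": [v.build for v in self.variants],
                "gene": [v.gene for v in self.variants],
            }
        )
        lab = pd.DataFrame(self.labels, columns=self.tissues)
        return pd.concat([head, lab], axis=1)

    def to_tsv(self, path_or_buffer) -> None:
        self.to_frame().to_csv(path_or_buffer, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "LabelMatrix":
        df = pd.read_csv(path_or_buffer, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        key_cols = ["chrom", "pos", "ref", "alt", "build", "gene"]
        tissues = [c for c in df.columns if c not in key_cols]
        variants = [
            VariantKey(r.chrom, int(r.pos), r.ref, r.alt, r.gene, r.build)
            for r in df[key_cols].itertuples(index=False)
        ]
        labels = df[tissues].to_numpy(dtype=np.int8)
        return cls(variants, tissues, labels, ~labels.any(axis=1))


@dataclass(frozen=True)
class FeatureMeta:
    """Origin, grouping, and imputation metadata for one feature column."""

    name: str
    origin: str  # "variant" | "tissue"
    group: str
    subgroup: str = ""
    tissue_tag: str | None = None
    impute_value: float = 0.0
    dtype: str = "numeric"  # "numeric" | "indicator"

    def __post_init__(self) -> None:
        if self.origin not in ("variant", "tissue"):
            raise ValueError(f"origin must be 'variant' or 'tissue', got {self.origin!r}")
        if self.origin == "tissue" and not self.tissue_tag:
            raise ValueError(f"tissue-specific feature {self.name!r} lacks a tissue_tag")
        if self.dtype not in ("numeric", "indicator"):
            raise ValueError(f"unknown dtype {self.dtype!r}")


def meta_to_json(meta: Sequence[FeatureMeta], path_or_buffer) -> None:
    payload = [vars(m) | {} for m in meta]
    if hasattr(path_or_buffer, "write"):
        json.dump(payload, path_or_buffer, indent=1)
    else:
        with open(path_or_buffer, "w") as fh:
            json.dump(payload, fh, indent=1)


def meta_from_json(path_or_buffer) -> list[FeatureMeta]:
    if hasattr(path_or_buffer, "read"):
        payload = json.load(path_or_buffer)
    else:
        with open(path_or_buffer) as fh:
            payload = json.load(fh)
    return [FeatureMeta(**d) for d in payload]


@dataclass
class FeatureTable:
    """Numeric variants x features matrix with column metadata."""

    variants: list[VariantKey]
    meta: list[FeatureMeta]
    values: pd.DataFrame  # index = variant id, columns = feature names

    def __post_init__(self) -> None:
        names = [m.name for m in self.meta]
        if list(self.values.columns) != names:
            raise SchemaError("feature values columns do not match metadata order")
        if len(self.values) != len(self.variants):
            raise SchemaError("feature row count does not match variant list")

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.meta]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, variant_ids: Sequence[str]) -> "FeatureTable":
        wanted = set(variant_ids)
        order = {vid: i for i, vid in enumerate(variant_ids)}
        pairs = sorted(
            ((order[v.id], v) for v in self.variants if v.id in wanted), key=lambda p: p[0]
        )
        if len(pairs) != len(wanted):
            missing = wanted - {v.id for v in self.variants}
            raise KeyError(f"variant ids absent from table: {sorted(missing)[:5]}")
        keys = [v for _, v in pairs]
        return FeatureTable(keys, self.meta, self.values.loc[[v.id for v in keys]])

    def to_tsv(self, path_or_buffer) -> None:
        head = pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "build": [v.build for v in self.variants],
                "gene": [v.gene for v in self.variants],
            },
            index=self.values.index,
        )
        pd.concat([head, self.values], axis=1).to_csv(
            path_or_buffer, sep="\t", index=False, float_format="%.12g"
        )

    @classmethod
    def from_tsv(cls, path_or_buffer, meta: Sequence[FeatureMeta]) -> "FeatureTable":
        df = pd.read_csv(path_or_buffer, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        key_cols = ["chrom", "pos", "ref", "alt", "build", "gene"]
        variants = [
            VariantKey(r.chrom, int(r.pos), r.ref, r.alt, r.gene, r.build)
            for r in df[key_cols].itertuples(index=False)
        ]
        names = [m.name for m in meta]
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise SchemaError(f"feature TSV lacks columns: {missing[:5]}")
        values = df[names].astype(float)
        values.index = pd.Index([v.id for v in variants])
        return cls(list(variants), list(meta), values)


# ---------------------------------------------------------------------------
# Parsing and labeling operations
# ---------------------------------------------------------------------------

_REQUIRED_RECORD_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "stars",
    "clin_sig_simple",
    "phenotype_omim_ids",
    "annotation_year",
)


def parse_clin_records(path_or_buffer) -> list[ClinRecord]:
    """Parse a delimited clinical-record table into :class:`ClinRecord` rows.

    Malformed rows are skipped with a logged warning naming the line
    number; a missing mandatory column raises :class:`SchemaError`, and so
    does a table in which every row is malformed.
    """
    if isinstance(path_or_buffer, str) and "\t" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"record table lacks mandatory columns: {missing}")
    records: list[ClinRecord] = []
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            phens = tuple(p for p in str(row.phenotype_omim_ids).replace(";", ",").split(",") if p)
            key = VariantKey(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                build=getattr(row, "build", "GRCh37") or "GRCh37",
            )
            records.append(
                ClinRecord(
                    key=key,
                    stars=int(row.stars),
                    clin_sig_simple=int(row.clin_sig_simple),
                    phenotype_omim_ids=phens,
                    annotation_year=int(row.annotation_year),
                )
            )
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping malformed record at line %d: %s", i, exc)
    if len(df) and not records:
        raise SchemaError("all record rows were malformed")
    return records


def select_reliable(records: Iterable[ClinRecord], min_stars: int = 2) -> list[ClinRecord]:
    """Keep records whose ClinVar review status has at least ``min_stars`` gold stars."""
    if min_stars < 0:
        raise ValueError("min_stars must be >= 0")
    return [r for r in records if r.stars >= min_stars]


def classify_pathogenic(record: ClinRecord, dmap: DiseaseTissueMap) -> frozenset[str]:
    """Affected tissues in which ``record`` is pathogenic (empty set = not pathogenic).

    The union over the record's OMIM ids of mapped affected tissues,
    restricted to diseases with a known molecular basis.  Ids unknown to
    the map are logged and ignored.
    """
    tissues: set[str] = set()
    for omim in record.phenotype_omim_ids:
        if omim not in dmap.tissues_of and omim not in dmap.molecular_basis:
            logger.info("OMIM id %s of %s not in the tissue map", omim, record.key.id)
            continue
        if omim in dmap.molecular_basis:
            tissues |= dmap.tissues_of.get(omim, frozenset())
    return frozenset(tissues)


def build_label_matrix(
    records: Sequence[ClinRecord],
    dmap: DiseaseTissueMap,
    tissues: Sequence[str],
    return_excluded: bool = False,
):
    """Build the binary variants x tissues label matrix.

    Pathogenic variants get 1 in each affected tissue and 0 elsewhere;
    benign records (ClinSigSimple 0, no disease link) get an all-zero row.
    Records qualifying as neither are excluded (and returned when
    ``return_excluded`` is set).  Duplicate keys are a hard error.
    """
    if not tissues:
        raise ValueError("tissue vocabulary must be non-empty")
    seen: dict[VariantKey, frozenset[str]] = {}
    order: list[ClinRecord] = []
    excluded: list[ClinRecord] = []
    for rec in records:
        affected = classify_pathogenic(rec, dmap)
        is_benign = rec.clin_sig_simple == 0 and not rec.phenotype_omim_ids
        if not affected and not is_benign:
            excluded.append(rec)
            continue
        if rec.key in seen:
            if seen[rec.key] != affected:
                raise ValueError(f"duplicate VariantKey with conflicting labels: {rec.key.id}")
            continue
        seen[rec.key] = affected
        order.append(rec)
    n, t = len(order), len(tissues)
    labels = np.zeros((n, t), dtype=np.int8)
    col = {tis: j for j, tis in enumerate(tissues)}
    for i, rec in enumerate(order):
        for tis in seen[rec.key]:
            if tis in col:
                labels[i, col[tis]] = 1
    matrix = LabelMatrix(
        variants=[r.key for r in order],
        tissues=list(tissues),
        labels=labels,
        is_benign_everywhere=~labels.any(axis=1),
    )
    if excluded:
        logger.info("excluded %d records qualifying as neither pathogenic nor benign", len(excluded))
    if return_excluded:
        return matrix, excluded
    return matrix


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------


def assemble_features(
    variant_features: pd.DataFrame,
    gene_features: pd.DataFrame,
    meta: Sequence[FeatureMeta],
    keys: Sequence[VariantKey],
    categorical_vocabs: Mapping[str, Sequence[str]] | None = None,
) -> FeatureTable:
    """Join per-variant and per-gene feature values into one table.

    ``variant_features`` is indexed by variant id and may contain raw
    categorical columns; ``gene_features`` is indexed by gene symbol.
    Categorical columns are expanded into the indicator columns declared in
    ``meta`` using the frozen vocabularies; an unseen level yields all-zero
    indicators with a warning.  A gene absent from ``gene_features`` leaves
    its tissue columns missing (NaN), to be imputed downstream.
    """
    categorical_vocabs = dict(categorical_vocabs or {})
    names = [m.name for m in meta]
    out = pd.DataFrame(np.nan, index=pd.Index([k.id for k in keys]), columns=names, dtype=float)

    # indicator columns grouped by their source categorical
    onehot_sources: dict[str, list[tuple[str, str]]] = {}
    for src, levels in categorical_vocabs.items():
        onehot_sources[src] = [(lvl, f"{src}__{lvl}") for lvl in levels]

    for src, pairs in onehot_sources.items():
        colnames = [c for _, c in pairs]
        absent = [c for c in colnames if c not in out.columns]
        if absent:
            raise SchemaError(f"meta lacks indicator columns for {src!r}: {absent[:3]}")
        if src not in variant_features.columns:
            continue
        raw = variant_features[src].reindex(out.index)
        known = {lvl for lvl, _ in pairs}
        unseen = set(raw.dropna().unique()) - known
        if unseen:
            logger.warning("unseen %s levels mapped to all-zero indicators: %s", src, sorted(unseen))
        for lvl, cname in pairs:
            out[cname] = (raw == lvl).astype(float)
            out.loc[raw.isna(), cname] = np.nan

    gene_of = {k.id: k.gene for k in keys}
    missing_genes = sorted({g for g in gene_of.values() if g not in gene_features.index})
    if missing_genes:
        logger.warning("genes absent from the gene feature table: %s", missing_genes[:5])

    genes = pd.Index([gene_of[i] for i in out.index])
    for m in meta:
        if m.dtype == "indicator":
            continue
        if m.origin == "variant":
            if m.name in variant_features.columns:
                out[m.name] = pd.to_numeric(
                    variant_features[m.name].reindex(out.index), errors="coerce"
                )
        else:
            if m.name in gene_features.columns:
                vals = gene_features[m.name].reindex(genes).to_numpy(dtype=float)
                out[m.name] = vals
    return FeatureTable(list(keys), list(meta), out)


def impute_missing(table: FeatureTable, meta: Sequence[FeatureMeta] | None = None) -> FeatureTable:
    """Fill missing cells: variant-specific defaults, zero for tissue-specific."""
    meta = list(meta if meta is not None else table.meta)
    fill = {}
    for m in meta:
        if m.impute_value is None:
            raise SchemaError(f"feature {m.name!r} has no impute_value")
        fill[m.name] = 0.0 if m.origin == "tissue" else float(m.impute_value)
    values = table.values.fillna(value=fill)
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise SchemaError(f"missing values remain after imputation in {bad[:5]}")
    return FeatureTable(table.variants, meta, values)


# ---------------------------------------------------------------------------
# Train / test split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    limited_test_ids: tuple[str, ...]
    excluded_test_ids: tuple[str, ...] = ()


def split_train_test(
    matrix: LabelMatrix, records: Sequence[ClinRecord], cutoff_year: int = 2022
) -> SplitResult:
    """Chronological train/test split with a gene-level leakage guard.

    Train = variants annotated by ``cutoff_year``.  Test = later variants,
    excluding any variant whose gene has training variants that all share
    one label class (all pathogenic or all benign).  The limited test set
    keeps only later variants in genes with no training variants at all.
    """
    year_of = {r.key.id: r.annotation_year for r in records}
    missing = [vid for vid in matrix.variant_ids if vid not in year_of]
    if missing:
        raise ValueError(f"variants without an annotation year: {missing[:5]}")
    is_path = matrix.labels.any(axis=1)
    train, later = [], []
    for i, v in enumerate(matrix.variants):
        (train if year_of[v.id] <= cutoff_year else later).append((i, v))

    gene_train_classes: dict[str, set[bool]] = {}
    for i, v in train:
        gene_train_classes.setdefault(v.gene, set()).add(bool(is_path[i]))

    test, limited, excluded = [], [], []
    for i, v in later:
        classes = gene_train_classes.get(v.gene)
        if classes is None:
            test.append(v.id)
            limited.append(v.id)
        elif len(classes) == 1:
            excluded.append(v.id)
        else:
            test.append(v.id)
    return SplitResult(
        train_ids=tuple(v.id for _, v in train),
        test_ids=tuple(test),
        limited_test_ids=tuple(limited),
        excluded_test_ids=tuple(excluded),
    )
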