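"""Default tissue vocabulary and feature catalogue.

The default schema combines 84 variant-specific features (11 groups,
CADD-style annotations consumed as columns) with 495 tissue-specific gene
features (expression, developmental expression, expression variability,
biological-process activity, eQTL, and interaction features across 14
tissues).  The catalogue here is a synthetic stand-in that reproduces the
aggregate structure of the real annotation sources — group sizes, per-
tissue coverage gaps (e.g. the kidney interaction features and the heart
eQTL features are unavailable), and the modeled-tissue partition sizes —
without shipping any third-party data.

Tissue-specific feature names follow ``{subgroup}_{i}__{tissue}``;
one-hot indicator columns follow ``{source}__{level}``.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

from .data_model import FeatureMeta

# ---------------------------------------------------------------------------
# Tissue vocabulary
# ---------------------------------------------------------------------------

TISSUES: tuple[str, ...] = (
    "whole_brain",
    "brain_cortex",
    "brain_cerebellum",
    "brain_basal_ganglia",
    "spinal_cord",
    "heart",
    "kidney",
    "liver",
    "lung",
    "skeletal_muscle",
    "skin",
    "testis",
    "nerve_tibial",
    "whole_blood",
)

BRAIN_SUBREGIONS: tuple[str, ...] = (
    "brain_cortex",
    "brain_cerebellum",
    "brain_basal_ganglia",
    "spinal_cord",
)

#: Modeled-tissue aliases: features tagged with any alias of tissue t count
#: as "features of the modeled tissue" when interpreting the model of t.
TISSUE_ALIASES: dict[str, tuple[str, ...]] = {
    **{t: (t,) for t in TISSUES},
    "whole_brain": ("whole_brain",) + BRAIN_SUBREGIONS,
    **{sub: (sub, "whole_brain") for sub in BRAIN_SUBREGIONS},
}

#: Tissues eligible for the single multi-tissue pair model: brain
#: subregions are excluded (near-duplicates of whole brain) and kidney is
#: excluded because it lacks the selected interaction feature.
MULTITISSUE_SET: tuple[str, ...] = tuple(
    t for t in TISSUES if t not in BRAIN_SUBREGIONS and t != "kidney"
)

# ---------------------------------------------------------------------------
# Variant-specific features: 84 columns in 11 groups
# ---------------------------------------------------------------------------

CONSEQUENCE_LEVELS: tuple[str, ...] = (
    "stop_gained",
    "frameshift",
    "missense",
    "synonymous",
    "splice_donor",
    "splice_acceptor",
    "splice_region",
    "inframe_insertion",
    "inframe_deletion",
    "start_lost",
    "stop_lost",
    "utr_5",
    "utr_3",
    "intronic",
    "upstream",
)

CATEGORICAL_VOCABS: dict[str, tuple[str, ...]] = {"consequence": CONSEQUENCE_LEVELS}

VARIANT_GROUPS: dict[str, tuple[str, ...]] = {
    "pathogenic_score": (
        "cadd_raw",
        "polyphen_hvar",
        "sift_score",
        "fathmm_score",
        "dann_score",
        "fitcons_score",
    ),
    "conservation": tuple(
        f"{stem}" for stem in (
            "gerp_n", "gerp_s", "gerp_rs",
            "phylop_primate", "phylop_mammal", "phylop_vertebrate",
            "phastcons_primate", "phastcons_mammal", "phastcons_vertebrate",
            "priphylop", "mamphylop", "verphylop",
        )
    ),
    "consequence": tuple(f"consequence__{lvl}" for lvl in CONSEQUENCE_LEVELS),
    "variant_location": tuple(
        ("cds_position", "relative_cds_position", "protein_position",
         "relative_protein_position", "exon_number", "intron_number",
         "distance_to_splice_site", "distance_to_tss", "gene_length", "cdna_position")
    ),
    "amino_acid": tuple(
        ("grantham_distance", "blosum62", "aa_volume_change", "aa_hydrophobicity_change",
         "aa_charge_change", "aa_polarity_change", "ref_aa_frequency", "alt_aa_frequency")
    ),
    "splicing": tuple(
        ("splice_ai_donor_gain", "splice_ai_donor_loss", "splice_ai_acceptor_gain",
         "splice_ai_acceptor_loss", "mmsp_donor_score", "mmsp_acceptor_score")
    ),
    "regulatory": tuple(
        ("encode_dnase", "encode_h3k27ac", "encode_h3k4me1", "encode_h3k4me3",
         "tf_binding_count", "motif_score_change", "mirna_target_score", "remap_overlap")
    ),
    "epigenetics": tuple(
        ("cpg_density", "gc_content", "methylation_level", "chromatin_state",
         "nucleosome_occupancy", "replication_timing", "lamin_b1_signal")
    ),
    "allele_frequency": tuple(
        ("gnomad_af", "thousand_genomes_af", "esp_af", "population_max_af")
    ),
    "protein_domain": tuple(
        ("in_pfam_domain", "domain_conservation", "disorder_score", "transmembrane_region")
    ),
    "gene_constraint": tuple(
        ("loeuf", "pli", "missense_z", "synonymous_z")
    ),
}

# ---------------------------------------------------------------------------
# Tissue-specific features: 495 columns in 6 main groups / 9 subgroups
# ---------------------------------------------------------------------------

#: subgroup -> main group ("a partition of the tissue features")
TISSUE_SUBGROUP_MAIN: dict[str, str] = {
    "expression": "expression",
    "preferential_expression": "expression",
    "expression_time": "expression_time",
    "expression_variability": "expression_variability",
    "process_activity": "biological_processes",
    "eqtl": "eqtl",
    "differential_ppi": "interactions",
    "elevated_ppi": "interactions",
    "paralog_ratio": "interactions",
}

_SUBGROUP_ORDER = tuple(TISSUE_SUBGROUP_MAIN)

_FULL = {
    "expression": 3,
    "preferential_expression": 3,
    "expression_time": 8,
    "expression_variability": 6,
    "process_activity": 8,
    "eqtl": 5,
    "differential_ppi": 4,
    "elevated_ppi": 5,
    "paralog_ratio": 3,
}  # 45 features

#: Per-tissue subgroup counts.  Coverage gaps mirror the heterogeneity of
#: the underlying omics sources: heart lacks eQTL features, kidney lacks
#: the elevated-interaction features, and the brain subregions carry a
#: reduced panel alongside the full whole-brain panel.
TISSUE_SUBGROUP_COUNTS: dict[str, dict[str, int]] = {
    "whole_brain": dict(_FULL),
    "brain_cortex": {
        "expression": 1, "preferential_expression": 1, "expression_time": 3,
        "expression_variability": 2, "process_activity": 3, "eqtl": 1,
        "differential_ppi": 1, "elevated_ppi": 2, "paralog_ratio": 1,
    },  # 15
    "brain_cerebellum": None,  # filled below (same as cortex)
    "brain_basal_ganglia": None,
    "spinal_cord": {
        "expression": 1, "preferential_expression": 1, "expression_time": 2,
        "expression_variability": 1, "process_activity": 3, "eqtl": 1,
        "differential_ppi": 1, "elevated_ppi": 1, "paralog_ratio": 1,
    },  # 12
    "heart": {**_FULL, "eqtl": 0, "elevated_ppi": 2, "paralog_ratio": 2},  # 36
    "kidney": {**_FULL, "eqtl": 7, "elevated_ppi": 0},  # 42
    "liver": dict(_FULL),
    "lung": dict(_FULL),
    "skeletal_muscle": dict(_FULL),
    "skin": dict(_FULL),
    "testis": dict(_FULL),
    "nerve_tibial": dict(_FULL),
    "whole_blood": dict(_FULL),
}
TISSUE_SUBGROUP_COUNTS["brain_cerebellum"] = dict(TISSUE_SUBGROUP_COUNTS["brain_cortex"])
TISSUE_SUBGROUP_COUNTS["brain_basal_ganglia"] = dict(TISSUE_SUBGROUP_COUNTS["brain_cortex"])

#: The five per-tissue feature selectors used by the multi-tissue pair
#: model; ``{t}`` is replaced by the tissue name.
PAIR_FEATURE_SELECTORS: dict[str, str] = {
    "preferential_expression": "preferential_expression_1__{t}",
    "expression": "expression_1__{t}",
    "developmental_expression": "expression_time_1__{t}",
    "process_activity": "process_activity_1__{t}",
    "tissue_ppi": "elevated_ppi_1__{t}",
}

SCHEMA_VERSION = "1.0"


@lru_cache(maxsize=1)
def _impute_defaults() -> dict:
    with resources.files("tracevar").joinpath("data/variant_impute_defaults.json").open() as fh:
        return json.load(fh)


def variant_impute_defaults() -> Mapping[str, float]:
    """Per-feature default fill values for the variant-specific columns."""
    return dict(_impute_defaults()["defaults"])


def tissue_feature_names(tissue: str) -> list[str]:
    counts = TISSUE_SUBGROUP_COUNTS[tissue]
    return [
        f"{sub}_{i}__{tissue}"
        for sub in _SUBGROUP_ORDER
        for i in range(1, counts[sub] + 1)
    ]


def default_feature_meta(tissues: Sequence[str] = TISSUES) -> list[FeatureMeta]:
    """Build the ordered default catalogue (579 columns for the 14 tissues)."""
    defaults = variant_impute_defaults()
    meta: list[FeatureMeta] = []
    for group, names in VARIANT_GROUPS.items():
        for name in names:
            indicator = name.startswith("consequence__")
            meta.append(
                FeatureMeta(
                    name=name,
                    origin="variant",
                    group=group,
                    subgroup=group,
                    tissue_tag=None,
                    impute_value=0.0 if indicator else float(defaults[name]),
                    dtype="indicator" if indicator else "numeric",
                )
            )
    for tissue in tissues:
        counts = TISSUE_SUBGROUP_COUNTS[tissue]
        for sub in _SUBGROUP_ORDER:
            for i in range(1, counts[sub] + 1):
                meta.append(
                    FeatureMeta(
                        name=f"{sub}_{i}__{tissue}",
                        origin="tissue",
                        group=TISSUE_SUBGROUP_MAIN[sub],
                        subgroup=sub,
                        tissue_tag=tissue,
                        impute_value=0.0,
                        dtype="numeric",
                    )
                )
    return meta


def pair_feature_columns(tissue: str) -> dict[str, str]:
    """Resolve the five multi-tissue selectors to concrete columns of ``tissue``."""
    available = set(tissue_feature_names(tissue))
    out: dict[str, str] = {}
    for sel, pattern in PAIR_FEATURE_SELECTORS.items():
        col = pattern.format(t=tissue)
        if col not in available:
            raise KeyError(f"selector {sel!r} unresolvable for tissue {tissue!r} ({col})")
        out[sel] = col
    return out
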