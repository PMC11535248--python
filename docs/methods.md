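# Methods

## Labeling model

A variant enters the dataset through a clinical record carrying review
stars, a clinical-significance flag, OMIM phenotype ids, and an annotation
year. Reliability filtering keeps records with ≥ 2 gold stars (multiple
concordant submitters). A retained record is *pathogenic in tissue t* when
at least one of its diseases has a known molecular basis (OMIM phenotype
mapping key 3) and clinically manifests in *t* according to the
disease→tissue map; a variant linked to several diseases receives the
union of their affected tissues. Records with significance flag 0 and no
disease link are *benign in every tissue*. Records satisfying neither rule
are excluded and reported. Duplicate variant keys with conflicting labels
are a hard error; variant identity is (chrom, pos, ref, alt, build) with
alleles taken as given — upstream tables are assumed pre-normalized, so no
left-alignment is attempted.

The chronological split places variants annotated by the cutoff year
(default 2022, inclusive) in training and later variants in test. A later
variant is excluded from test when its gene's training variants all share
one label class (such a gene's class is effectively known); the *limited*
test set keeps only later variants in genes with no training variants at
all. This mirrors the leakage concern that motivates gene-aware
evaluation everywhere in the package.

## Feature schema

The default catalogue has 579 columns: 84 variant-specific features in 11
groups (pathogenicity scores, conservation, a 15-level one-hot consequence
vocabulary, variant location, amino-acid change, splicing, regulatory,
epigenetics, allele frequency, protein domain, gene constraint) and 495
tissue-specific gene features in 6 main groups over 9 subgroups
(expression and preferential expression; developmental expression;
expression variability; biological-process activity; eQTL; differential
and elevated tissue interactions and paralog compensation) across 14
tissues (whole brain plus four brain subregions, heart, kidney, liver,
lung, skeletal muscle, skin, testis, tibial nerve, whole blood). The
catalogue is a synthetic stand-in for the real annotation sources: it
reproduces their aggregate structure — per-group counts, per-tissue
coverage gaps (heart lacks eQTL features; kidney lacks the elevated-
interaction features), and the modeled-tissue partition sizes (84/36/459
for the heart model, 84/102/393 for whole brain, whose aliases include the
subregions) — without shipping third-party data. Exact names and defaults
live in `schema.py` and `data/variant_impute_defaults.json` (versioned).

Missing values are imputed per column: variant-specific columns use the
configured defaults (neutral values of each annotation; e.g. a tolerated
SIFT score of 1.0, zero conservation), tissue-specific columns use zero.
One-hot vocabularies are frozen in the schema; unseen categorical levels
map to all-zero indicators with a warning rather than erroring, so
scoring never fails on novel annotation output.

## Cross-validation folds

Folds satisfy two constraints: no gene spans two folds, and each fold's
pathogenic fraction stays within a relative tolerance (default 10% — the
qualitative requirement is "similar", which we quantify here) of the
tissue's overall pathogenic fraction. Construction is deterministic given
the seed: gene groups containing pathogenic variants are assigned largest
first to the fold currently lightest in positives; benign-only gene groups
are then drawn in seeded random order, largest first, each joining the
fold with the highest remaining pathogenic fraction, capped by the
tolerance window; a final repair pass moves groups from oversupplied to
starved folds. Benign groups that fit nowhere are unused for that tissue's
cross-validation. The fold count, when not given, is
`min(15, max(2, n_pathogenic_genes // 4))` — a transparent surrogate rule
calibrated so that sparse tissues get 2 folds and the largest get 15;
the published analyses report the resulting counts but not the generating
rule, so the divisor is configurable. Tissues with pathogenic variants in
fewer than 20 genes are rejected unless explicitly overridden.

## Learner

The per-tissue classifier is a gradient-boosted decision-tree ensemble
(xgboost, binary logistic objective) with defaults of 100 trees, depth 3,
learning rate 0.1, fitted single-threaded with a fixed seed; identical
inputs and seed give bit-identical models and scores. xgboost was chosen
over other gradient-boosting implementations because it exposes exact
tree dumps (needed for the float64 Shapley implementation below) and a
stable single-file serialization; any scikit-learn-style classifier can
be substituted for method comparisons, but explanations require a tree
ensemble. Hyperparameters are tuned by seeded random search (default 25
draws over tree count 50–300, depth 2–6, log-uniform learning rate
0.01–0.3, subsample 0.6–1, minimum child weight 1–10) maximizing the mean
per-fold validation auPRC; pooled scoring across folds is available
behind a flag because the averaging convention is a genuine free choice.
auPRC drives tuning because at ~1.7% prevalence auROC saturates long
before the top of the ranking is clean.

Model archives store the serialized booster with its feature schema,
hyperparameters, seed and framework version, and scoring refuses tables
whose column list does not match the schema exactly.

## Metrics and statistics

auROC uses the rank (Mann–Whitney) formulation with ties counted ½;
auPRC is average precision with step interpolation (trapezoidal
interpolation is optimistic on precision–recall curves), reported next to
its random baseline, the positive prevalence. Method comparison always
recomputes both scorings on the intersection of variants scored by both
methods. The hybrid baseline is the arithmetic mean of a tissue-oblivious
variant score and a tissue-aware gene score.

The one-tailed paired Wilcoxon signed-rank test drops zero differences,
uses the exact null distribution for n ≤ 25 (a subset-sum dynamic program
over tie-averaged ranks doubled to integers, equivalent to full sign
enumeration), and a normal approximation with continuity and tie
correction beyond. The one-tailed Mann–Whitney test is exact for
min(n, m) ≤ 8 without ties and tie-corrected asymptotic otherwise; a
sample pool with every value identical returns p = 0.5 (the exchangeable
null carries no evidence in either direction). Multiple tests are
adjusted with Benjamini–Hochberg. Percentile ranks assign rank 1 to the
highest score with average ranks on ties; percentile = rank / n, and
"above the median" is the strict reading percentile < 0.5.

## Interpretation

Shapley attributions are computed by the path-dependent polynomial
algorithm for tree ensembles, implemented here in float64 over the
booster's dumped trees (conditional expectations for out-of-coalition
features follow training cover fractions at each split; feature routing
mirrors the booster's float32 comparisons exactly). Attributions live in
margin (log-odds) space where local accuracy is exact: base value plus
attributions reproduces the float64 ensemble margin to ~1e-8. The test
suite verifies the implementation against a power-set coalition
enumeration oracle on small models and against the booster's built-in
float32 contributions.

Feature importance is the median *absolute* attribution across variants
(default: the model's training variants; configurable): a signed median
cancels bidirectional effects and contradicts ordering features by
absolute contribution, though a signed mode exists. Group importance
normalizes per-feature importances to sum to one and averages them within
groups; each tissue subgroup is reported twice (modeled-tissue members
versus other-tissue members, using the tissue alias table so the whole-
brain model owns the subregion features) and the differential- and
elevated-interaction subgroups merge into one interaction group.
Feature-class ranking covers all features (never a truncated top set),
compares modeled-tissue against variant-specific and against other-tissue
features with one-tailed Mann–Whitney tests (BH-adjusted), and a
collective mode compares per-model median ranks across tissue models with
one-tailed paired Wilcoxon tests.

## Multi-tissue pair model

The pair dataset carries one row per (variant, tissue): 84 variant
features plus five selected features of the paired tissue (preferential
expression, absolute expression, developmental expression, process
activity, tissue interaction score — configurable selectors resolved per
tissue). The default tissue set excludes the four brain subregions
(near-duplicates of whole brain would leak across folds) and kidney
(missing the interaction selector), leaving 9 of the 14. Evaluation is
leave-one-tissue-out: train on eight tissues' pairs, score the ninth's.

## Clinical prioritization

Candidate filtration keeps variants that pass upstream read-quality and
region flags (supplied as booleans — they require alignment-level data
this package does not consume), have maximum population allele frequency
strictly below 0.5% (a frequency equal to the cutoff is excluded), look
possibly deleterious (loss-of-function, missense, or splice-altering
consequence, or CADD score strictly above 15), and carry a zygosity
allowed under the case's mode of inheritance (recessive → homozygous or
compound-heterozygous; X-linked recessive → hemizygous or homozygous;
dominant modes → any; configurable). The filter is a conjunction, hence
order-independent.

Prioritization trains the affected tissue's model either on the full
labeled dataset or, in case-specific mode, excluding every variant that
shares a gene with any candidate (the leakage-guarded variant), scores
the candidates, and ranks them descending with average ranks on ties. A
two-tissue patient yields two ranked lists. The per-case outcome is the
verified variant's rank and percentile; cohort summaries report fractions
above the median (strict), in the top quartile, and in the top decile.

## Synthetic data generator

The generator defines the study conditions under which the package is
validated. Genes receive standard-normal baseline tissue profiles; per
tissue, a disjoint set of genes is designated pathogenic-in-that-tissue
and its modeled-tissue features (including alias tissues) are shifted
additively by the per-subgroup `tissue_effect` (default 1.5 on every
subgroup — a strong but not degenerate separation emulating the
preferential expression and activity of disease genes in affected
tissues). Within a pathogenic gene, 60% of variants are pathogenic; the
rest are benign, so gene-level features alone cannot separate classes.
Pathogenic variants draw their six pathogenicity-score features from
Beta(2 + 4·`variant_effect`, 8) against a benign Beta(2, 8) (default
effect 1.0, a moderate overlap), and their consequence class from a
deleterious-leaning categorical whose shift scales with `variant_effect`
and vanishes at zero. All other variant features are noise. Per-tissue
pathogenic prevalence defaults to 1.7%, the median per-tissue rate of the
kind of curated clinical-variant dataset this emulates; records receive
annotation years uniform on 2016–2024 and stars in {2, 3, 4} so the
chronological split and reliability filter are exercised; a 5% missing-
cell rate exercises imputation. Under `interaction=True`, benign decoys
with only one of the two signals are added — deleterious-looking variants
in unremarkable genes, and tissue-shifted genes with only benign
variants — making pathogenicity an AND of both signals, the regime where
a post hoc score average is structurally disadvantaged against the
integrated model.

What the generator does *not* emulate: correlated expression across
tissues and genes, realistic allele-frequency spectra, linkage between
consequence class and position, or annotation noise that correlates with
gene identity. Passing tests therefore demonstrate that the machinery
recovers planted signal under controlled conditions, not that real-data
performance reaches any particular level.

Patient cases draw n − 1 background candidates from the benign
distribution in the post-filtration regime (rare alleles, mostly
deleterious-looking consequence or CADD above 15) plus one planted
variant carrying both signals for the affected tissue; the default case
size of 241 candidates matches the median of the clinical cohorts this
emulates.

## Problem sizes and numerical choices

The acceptance script runs six-tissue studies at 5,000 variants in 400
genes (the interaction study at 3,000 variants; 20 clinical cases of 241
candidates) with 60-tree models — sizes chosen so a complete run takes
about a minute on one CPU while keeping ≥ 80 pathogenic variants per
tissue. The test suite uses the same generator at 600–5,000 variants per
scenario. Numerical conventions: TSV writers print floats with %.12g
(bit-stable round-trips at float64 precision for the values produced
here); Shapley local accuracy is asserted at 1e-6 against the float64
ensemble margin; metric implementations are asserted at 1e-12 against
enumeration oracles; seeded generators are the only randomness source, so
every pipeline stage is byte-reproducible.

## Known limitations

No liftover between genome builds; no retrieval from variant or phenotype
services; tissue features are consumed as a gene table, never derived
from raw expression data; external predictor scores are consumed as
columns, never re-derived; no compound-heterozygote detection from
genotypes; explanations require the tree-ensemble learner. The default
feature catalogue is synthetic in the sense described above — users with
real annotation tables supply their own `FeatureMeta` list and the rest
of the pipeline is unchanged.
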