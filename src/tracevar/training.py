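"""Per-tissue gradient-boosted classifiers and the multi-tissue pair model.

The default learner is a gradient-boosted decision-tree ensemble
(xgboost) with conservative defaults — 100 trees, depth 3, learning rate
0.1 — fitted single-threaded with a fixed seed so identical inputs give
identical models.  Hyperparameters are tuned by seeded random search
maximizing the mean validation auPRC over gene-disjoint folds, the
relevant objective for the ~1.7% pathogenic prevalence of a typical
tissue.

The multi-tissue model reshapes the dataset into (variant, tissue) pairs:
each pair carries the variant's 84 variant-specific features plus five
selected features of the paired tissue (89 in total), is labeled by the
variant's pathogenicity in that tissue, and is evaluated leave-one-
tissue-out.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost

from . import schema
from .data_model import FeatureTable, LabelMatrix, SchemaError
from .evaluation import auprc
from .folds import FoldPlan

DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 1.0,
    "min_child_weight": 1,
}

#: Random-search space: (low, high) TUPLES are ranges sampled uniformly
#: (log-uniform for the learning rate, integers for integer parameters);
#: lists are explicit choices sampled uniformly.
DEFAULT_SEARCH_SPACE: dict = {
    "n_estimators": (50, 300),
    "max_depth": (2, 6),
    "learning_rate": (0.01, 0.3),
    "subsample": (0.6, 1.0),
    "min_child_weight": (1, 10),
}

_INT_PARAMS = {"n_estimators", "max_depth", "min_child_weight"}
_LOG_PARAMS = {"learning_rate"}


@dataclass
class TissueModel:
    """A fitted tissue-specific classifier with its provenance metadata."""

    tissue: str
    learner: xgboost.XGBClassifier
    hyperparams: dict
    feature_schema: list[str]
    train_ids: list[str]
    seed: int
    framework_version: str = xgboost.__version__

    def save(self, path: str) -> None:
        """Single-file JSON archive: serialized booster + metadata."""
        raw = self.learner.get_booster().save_raw(raw_format="json")
        payload = {
            "tissue": self.tissue,
            "hyperparams": self.hyperparams,
            "feature_schema": self.feature_schema,
            "train_ids": self.train_ids,
            "seed": self.seed,
            "framework_version": self.framework_version,
            "booster_b64": base64.b64encode(bytes(raw)).decode("ascii"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "TissueModel":
        with open(path) as fh:
            payload = json.load(fh)
        learner = _make_learner(payload["hyperparams"], payload["seed"])
        learner.load_model(bytearray(base64.b64decode(payload["booster_b64"])))
        return cls(
            tissue=payload["tissue"],
            learner=learner,
            hyperparams=payload["hyperparams"],
            feature_schema=payload["feature_schema"],
            train_ids=payload["train_ids"],
            seed=payload["seed"],
            framework_version=payload["framework_version"],
        )

    def booster(self) -> xgboost.Booster:
        return self.learner.get_booster()


@dataclass
class PredictionResult:
    variant_ids: list[str]
    tissue: str
    scores: np.ndarray  # pathogenic probability per variant

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != len(self.variant_ids):
            raise ValueError("one score per variant id required")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


def _make_learner(hyperparams: Mapping, seed: int) -> xgboost.XGBClassifier:
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    return xgboost.XGBClassifier(
        n_estimators=int(hp["n_estimators"]),
        max_depth=int(hp["max_depth"]),
        learning_rate=float(hp["learning_rate"]),
        subsample=float(hp["subsample"]),
        min_child_weight=float(hp["min_child_weight"]),
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed),
        base_score=0.5,
        eval_metric="logloss",
    )


def fit_tissue_model(
    features: FeatureTable,
    labels: Sequence[int],
    tissue: str = "",
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> TissueModel:
    """Fit a gradient-boosted classifier for one tissue's labels.

    Labels must align row-for-row with ``features`` and contain both
    classes; the fit is fully deterministic given the seed.
    """
    y = np.asarray(labels)
    if y.size != len(features.variants):
        raise SchemaError("labels are not aligned with the feature rows")
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    learner = _make_learner(hp, seed)
    learner.fit(features.matrix(), y)
    return TissueModel(
        tissue=tissue,
        learner=learner,
        hyperparams=hp,
        feature_schema=list(features.feature_names),
        train_ids=list(features.variant_ids),
        seed=seed,
    )


def predict_scores(model: TissueModel, features: FeatureTable) -> PredictionResult:
    """Pathogenic probability per variant under ``model``."""
    if list(features.feature_names) != list(model.feature_schema):
        missing = set(model.feature_schema) - set(features.feature_names)
        extra = set(features.feature_names) - set(model.feature_schema)
        raise SchemaError(
            f"feature schema mismatch (missing: {sorted(missing)[:3]}, extra: {sorted(extra)[:3]})"
        )
    if not features.variants:
        return PredictionResult([], model.tissue, np.empty(0))
    proba = model.learner.predict_proba(features.matrix())[:, 1]
    return PredictionResult(list(features.variant_ids), model.tissue, proba)


def _sample_config(space: Mapping, rng: np.random.Generator) -> dict:
    cfg = {}
    for name, bounds in space.items():
        if isinstance(bounds, tuple) and len(bounds) == 2:
            lo, hi = bounds
            if name in _INT_PARAMS:
                cfg[name] = int(rng.integers(int(lo), int(hi) + 1))
            elif name in _LOG_PARAMS:
                cfg[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                cfg[name] = float(rng.uniform(lo, hi))
        else:  # explicit choices
            cfg[name] = bounds[int(rng.integers(len(bounds)))]
    return cfg


def tune_hyperparameters(
    features: FeatureTable,
    labels: Sequence[int],
    fold_plan: FoldPlan,
    space: Mapping | None = None,
    n_iter: int = 25,
    seed: int = 0,
    pooled: bool = False,
) -> tuple[dict, list[dict]]:
    """Seeded random search maximizing cross-validated auPRC.

    Samples ``n_iter`` configurations uniformly from ``space`` and scores
    each by the mean validation auPRC over the plan's folds (``pooled``
    instead concatenates all fold predictions and scores them once).
    Returns the best configuration (ties break toward the first sampled)
    and the full search log.
    """
    space = dict(space if space is not None else DEFAULT_SEARCH_SPACE)
    if not space:
        raise ValueError("hyperparameter space is empty")
    y = pd.Series(np.asarray(labels), index=features.variant_ids)
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best: dict | None = None
    best_score = -np.inf
    for it in range(n_iter):
        cfg = _sample_config(space, rng)
        fold_scores = []
        pooled_scores, pooled_labels = [], []
        for f in range(fold_plan.n_folds):
            val_ids = fold_plan.folds[f]
            train_ids = [v for g in range(fold_plan.n_folds) if g != f for v in fold_plan.folds[g]]
            m = fit_tissue_model(
                features.subset(train_ids), y.loc[train_ids].to_numpy(),
                fold_plan.tissue, cfg, seed,
            )
            s = predict_scores(m, features.subset(val_ids)).scores
            yv = y.loc[val_ids].to_numpy()
            if pooled:
                pooled_scores.append(s)
                pooled_labels.append(yv)
            else:
                fold_scores.append(auprc(s, yv)[0])
        if pooled:
            score = auprc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))[0]
        else:
            score = float(np.mean(fold_scores))
        log.append({"iteration": it, "config": cfg, "mean_auprc": score})
        if score > best_score:
            best_score, best = score, cfg
    return dict(best), log


def leave_gene_out_scores(
    features: FeatureTable,
    label_matrix: LabelMatrix,
    gene: str,
    tissues: Sequence[str],
    seed: int = 0,
    hyperparams: Mapping | None = None,
) -> dict[str, PredictionResult]:
    """Score one gene's variants under models trained without that gene.

    For each tissue, a model is fitted on every variant except the target
    gene's, then applied to the target gene's variants — the proof-of-
    concept protocol for tissue-specific scoring.
    """
    gene_ids = [v.id for v in features.variants if v.gene == gene]
    if not gene_ids:
        raise ValueError(f"gene {gene!r} has no variants in the dataset")
    rest_ids = [v.id for v in features.variants if v.gene != gene]
    rest = features.subset(rest_ids)
    target = features.subset(gene_ids)
    row = {vid: i for i, vid in enumerate(label_matrix.variant_ids)}
    out: dict[str, PredictionResult] = {}
    for t in tissues:
        y = label_matrix.column(t)[[row[v] for v in rest_ids]]
        model = fit_tissue_model(rest, y, t, hyperparams, seed)
        out[t] = predict_scores(model, target)
    return out


# ---------------------------------------------------------------------------
# Multi-tissue (variant, tissue)-pair model
# ---------------------------------------------------------------------------


@dataclass
class PairDataset:
    """Rows of (variant, tissue) pairs with 84 + 5 features and pair labels."""

    pairs: pd.DataFrame  # columns: variant_id, tissue
    X: np.ndarray  # shape (n_pairs, 89)
    y: np.ndarray
    feature_names: list[str]
    tissues: list[str]


def build_pair_dataset(
    label_matrix: LabelMatrix,
    features: FeatureTable,
    tissue_feature_names: Mapping[str, str] | None = None,
    tissues: Sequence[str] | None = None,
) -> PairDataset:
    """Reshape variants x tissues into pair rows.

    Row (v, t) carries v's variant-specific features plus the five
    selected tissue features evaluated at t; its label is the label
    matrix entry for (v, t).  ``tissue_feature_names`` maps selector
    names to per-tissue column patterns with a ``{t}`` placeholder.
    """
    tissues = list(tissues if tissues is not None else schema.MULTITISSUE_SET)
    patterns = dict(tissue_feature_names or schema.PAIR_FEATURE_SELECTORS)
    variant_cols = [m.name for m in features.meta if m.origin == "variant"]
    col_set = set(features.feature_names)
    per_tissue_cols: dict[str, list[str]] = {}
    for t in tissues:
        cols = []
        for sel, pattern in patterns.items():
            c = pattern.format(t=t)
            if c not in col_set:
                raise SchemaError(f"selector {sel!r} unresolvable for tissue {t!r}: {c}")
            cols.append(c)
        per_tissue_cols[t] = cols

    vids = features.variant_ids
    row = {vid: i for i, vid in enumerate(label_matrix.variant_ids)}
    Xv = features.values[variant_cols].to_numpy(dtype=float)
    blocks, labels, pair_rows = [], [], []
    for t in tissues:
        Xt = features.values[per_tissue_cols[t]].to_numpy(dtype=float)
        blocks.append(np.hstack([Xv, Xt]))
        labels.append(label_matrix.column(t)[[row[v] for v in vids]])
        pair_rows.extend((v, t) for v in vids)
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    names = variant_cols + [f"pair__{sel}" for sel in patterns]
    pairs = pd.DataFrame(pair_rows, columns=["variant_id", "tissue"])
    return PairDataset(pairs, X, y, names, tissues)


def fit_multitissue_loto(
    pair_dataset: PairDataset,
    left_out_tissue: str,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> tuple[xgboost.XGBClassifier, PredictionResult]:
    """Train on all pairs of the other tissues; score the left-out tissue's pairs."""
    if left_out_tissue not in pair_dataset.tissues:
        raise ValueError(f"tissue {left_out_tissue!r} absent from the pair dataset")
    mask = (pair_dataset.pairs["tissue"] == left_out_tissue).to_numpy()
    learner = _make_learner(hyperparams or {}, seed)
    learner.fit(pair_dataset.X[~mask], pair_dataset.y[~mask])
    proba = learner.predict_proba(pair_dataset.X[mask])[:, 1]
    ids = pair_dataset.pairs.loc[mask, "variant_id"].tolist()
    return learner, PredictionResult(ids, left_out_tissue, proba)
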