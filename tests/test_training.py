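"""Model fitting, tuning, leave-gene-out scoring, and the pair model."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_toy_table
from tracevar import (
    FoldPlan,
    SchemaError,
    SimConfig,
    TissueModel,
    auroc,
    build_pair_dataset,
    fit_multitissue_loto,
    fit_tissue_model,
    generate_leave_gene_out_scenario,
    impute_missing,
    leave_gene_out_scores,
    predict_scores,
    schema,
    tune_hyperparameters,
)

FAST = {"n_estimators": 40, "max_depth": 3}


def separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] = np.where(y, X[:, 0] + 3, X[:, 0] - 3)  # feature 0 separates perfectly
    return make_toy_table(X), y


class TestFit:
    def test_separable_toy_reaches_training_auroc_one(self):
        table, y = separable_toy()
        m = fit_tissue_model(table, y, "heart", FAST, seed=0)
        s = predict_scores(m, table).scores
        assert auroc(s, y) == 1.0

    def test_same_seed_reproduces_scores_elementwise(self):
        table, y = separable_toy(seed=3)
        s1 = predict_scores(fit_tissue_model(table, y, "heart", FAST, seed=5), table).scores
        s2 = predict_scores(fit_tissue_model(table, y, "heart", FAST, seed=5), table).scores
        assert np.array_equal(s1, s2)

    def test_single_class_labels_raise(self):
        table, _ = separable_toy()
        with pytest.raises(ValueError, match="single class"):
            fit_tissue_model(table, np.ones(len(table.variants)), "heart")

    def test_misaligned_labels_raise(self):
        table, y = separable_toy()
        with pytest.raises(SchemaError):
            fit_tissue_model(table, y[:-1], "heart")


class TestPredict:
    def test_scores_are_probabilities(self):
        table, y = separable_toy(seed=1)
        m = fit_tissue_model(table, y, "heart", FAST)
        s = predict_scores(m, table).scores
        assert (s >= 0).all() and (s <= 1).all()

    def test_schema_mismatch_names_columns(self):
        table, y = separable_toy()
        m = fit_tissue_model(table, y, "heart", FAST)
        bad = make_toy_table(np.zeros((3, 3)))
        with pytest.raises(SchemaError, match="missing"):
            predict_scores(m, bad)

    def test_empty_input_gives_empty_result(self):
        table, y = separable_toy()
        m = fit_tissue_model(table, y, "heart", FAST)
        empty = table.subset([])
        res = predict_scores(m, empty)
        assert res.variant_ids == [] and res.scores.size == 0

    def test_pathogenic_like_variant_scores_high(self):
        table, y = separable_toy(seed=2)
        m = fit_tissue_model(table, y, "heart", FAST)
        pos_ids = [v for v, l in zip(table.variant_ids, y) if l == 1]
        s = predict_scores(m, table.subset(pos_ids[:5])).scores
        assert (s > 0.5).all()


class TestSerialization:
    def test_save_load_round_trip_bit_identical_scores(self, tmp_path):
        table, y = separable_toy(seed=4)
        m = fit_tissue_model(table, y, "heart", FAST, seed=9)
        path = tmp_path / "heart.model"
        m.save(str(path))
        back = TissueModel.load(str(path))
        assert back.tissue == "heart" and back.seed == 9
        assert back.feature_schema == m.feature_schema
        s1 = predict_scores(m, table).scores
        s2 = predict_scores(back, table).scores
        assert np.array_equal(s1, s2)


class TestTuning:
    def _plan(self, table, y, n_folds=2, seed=0):
        ids = np.array(table.variant_ids)
        folds = [list(ids[i::n_folds]) for i in range(n_folds)]
        return FoldPlan("heart", folds, n_folds, float(np.mean(y)), seed)

    def test_single_iteration_returns_that_config(self):
        table, y = separable_toy(n=60, seed=6)
        plan = self._plan(table, y)
        best, log = tune_hyperparameters(table, y, plan, n_iter=1, seed=0)
        assert len(log) == 1 and best == log[0]["config"]

    def test_crippled_config_loses_to_sound_one(self):
        # evaluate a sound and a crippled configuration by the same CV
        # machinery (singleton spaces) and compare their mean auPRC
        table, y = separable_toy(n=80, seed=7)
        plan = self._plan(table, y)
        good = {"n_estimators": [60], "max_depth": [3], "learning_rate": [0.1]}
        crippled = {"n_estimators": [1], "max_depth": [1], "learning_rate": [0.001]}
        _, log_good = tune_hyperparameters(table, y, plan, space=good, n_iter=1, seed=0)
        _, log_bad = tune_hyperparameters(table, y, plan, space=crippled, n_iter=1, seed=0)
        assert log_good[0]["mean_auprc"] > log_bad[0]["mean_auprc"]

    def test_search_log_is_deterministic(self):
        table, y = separable_toy(n=60, seed=8)
        plan = self._plan(table, y)
        _, log1 = tune_hyperparameters(table, y, plan, n_iter=4, seed=3)
        _, log2 = tune_hyperparameters(table, y, plan, n_iter=4, seed=3)
        assert log1 == log2

    def test_empty_space_raises(self):
        table, y = separable_toy()
        plan = self._plan(table, y)
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(table, y, plan, space={}, n_iter=2)


class TestLeaveGeneOut:
    @pytest.fixture(scope="class")
    def scenario(self):
        cfg = SimConfig(
            n_genes=120, n_variants=1200,
            tissues=("heart", "liver", "lung", "skeletal_muscle", "skin", "whole_blood"),
            seed=21,
        )
        sim, gene = generate_leave_gene_out_scenario(cfg, "heart")
        features = impute_missing(sim.features)
        return sim, gene, features

    def test_excluded_gene_never_in_training_ids(self, scenario):
        sim, gene, features = scenario
        out = leave_gene_out_scores(features, sim.labels, gene, ["heart", "liver"], seed=0,
                                    hyperparams=FAST)
        gene_ids = {v.id for v in features.variants if v.gene == gene}
        for t in ("heart", "liver"):
            assert set(out[t].variant_ids) == gene_ids

    def test_pathogenic_variants_score_higher_in_affected_tissue(self, scenario):
        sim, gene, features = scenario
        tissues = list(sim.labels.tissues)
        out = leave_gene_out_scores(features, sim.labels, gene, tissues, seed=0, hyperparams=FAST)
        row = {v: i for i, v in enumerate(sim.labels.variant_ids)}
        y_heart = sim.labels.column("heart")
        path_ids = [v for v in out["heart"].variant_ids if y_heart[row[v]] == 1]
        idx = [out["heart"].variant_ids.index(v) for v in path_ids]
        heart_scores = out["heart"].scores[idx]
        for t in tissues:
            if t == "heart":
                continue
            other = out[t].scores[[out[t].variant_ids.index(v) for v in path_ids]]
            assert heart_scores.mean() > other.mean()

    def test_benign_variants_score_low_everywhere(self, scenario):
        sim, gene, features = scenario
        tissues = list(sim.labels.tissues)
        out = leave_gene_out_scores(features, sim.labels, gene, tissues, seed=0, hyperparams=FAST)
        row = {v: i for i, v in enumerate(sim.labels.variant_ids)}
        benign = [v for v in out["heart"].variant_ids if not sim.labels.labels[row[v]].any()]
        for t in tissues:
            s = out[t].scores[[out[t].variant_ids.index(v) for v in benign]]
            assert np.median(s) < 0.5

    def test_absent_gene_raises(self, scenario):
        sim, _, features = scenario
        with pytest.raises(ValueError, match="NOPE"):
            leave_gene_out_scores(features, sim.labels, "NOPE", ["heart"])


class TestPairModel:
    @pytest.fixture(scope="class")
    def pairs(self, small_sim, small_features):
        tissues = [t for t in small_sim.labels.tissues]
        return build_pair_dataset(small_sim.labels, small_features, tissues=tissues)

    def test_cardinality_and_width(self, pairs, small_sim):
        n_v = len(small_sim.labels.variants)
        n_t = len(small_sim.labels.tissues)
        assert len(pairs.pairs) == n_v * n_t
        assert pairs.X.shape[1] == 84 + 5

    def test_pair_labels_match_matrix(self, pairs, small_sim):
        row = {v: i for i, v in enumerate(small_sim.labels.variant_ids)}
        sample = pairs.pairs.sample(50, random_state=0)
        for (vid, t), y in zip(sample.itertuples(index=False), pairs.y[sample.index]):
            assert y == small_sim.labels.labels[row[vid], small_sim.labels.tissues.index(t)]

    def test_default_tissue_set_excludes_brain_subregions_and_kidney(self):
        assert "kidney" not in schema.MULTITISSUE_SET
        assert not set(schema.BRAIN_SUBREGIONS) & set(schema.MULTITISSUE_SET)
        assert len(schema.MULTITISSUE_SET) == 9

    def test_unresolvable_selector_raises(self, small_sim, small_features):
        with pytest.raises(SchemaError, match="unresolvable"):
            build_pair_dataset(
                small_sim.labels, small_features,
                tissue_feature_names={"bogus": "no_such_col__{t}"},
                tissues=["heart"],
            )

    def test_left_out_tissue_not_in_training_rows(self, pairs):
        model, res = fit_multitissue_loto(pairs, "heart", FAST, seed=0)
        assert res.tissue == "heart"
        mask = (pairs.pairs["tissue"] == "heart").to_numpy()
        assert len(res.variant_ids) == int(mask.sum())

    def test_transferable_signal_gives_above_chance_loto_auroc(self, pairs):
        _, res = fit_multitissue_loto(pairs, "liver", FAST, seed=0)
        mask = (pairs.pairs["tissue"] == "liver").to_numpy()
        y = pairs.y[mask]
        assert auroc(res.scores, y) > 0.6

    def test_loto_deterministic_under_seed(self, pairs):
        _, r1 = fit_multitissue_loto(pairs, "skin", FAST, seed=4)
        _, r2 = fit_multitissue_loto(pairs, "skin", FAST, seed=4)
        assert np.array_equal(r1.scores, r2.scores)

    def test_absent_tissue_raises(self, pairs):
        with pytest.raises(ValueError, match="absent"):
            fit_multitissue_loto(pairs, "testis")


class TestMonotoneResponse:
    def test_score_does_not_decrease_with_planted_signal(self):
        # average over seeds: raising the separating feature never lowers
        # the mean score on a grid (tree ensembles are piecewise constant)
        deltas = []
        for seed in range(20):
            table, y = separable_toy(n=60, seed=seed)
            m = fit_tissue_model(table, y, "heart", FAST, seed=seed)
            base = table.values.copy()
            grid = np.linspace(-3, 3, 7)
            means = []
            for g in grid:
                mod = base.copy()
                mod["x0"] = g
                probe = type(table)(table.variants, table.meta, mod)
                means.append(predict_scores(m, probe).scores.mean())
            deltas.append(np.diff(means))
        assert np.mean(np.concatenate(deltas)) >= 0
        assert np.all(np.mean(deltas, axis=0) >= -1e-6)
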