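"""Shapley attributions, importance aggregation, and feature-class ranks."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_toy_table
from tracevar import (
    FeatureMeta,
    SimConfig,
    explain_variant,
    feature_importance,
    fit_tissue_model,
    generate_dataset,
    group_importance,
    impute_missing,
    margin_scores,
    partition_features,
    rank_feature_classes,
    rank_feature_classes_collective,
    schema,
    shap_explain,
)
from tracevar.interpretation import _booster_trees


def fitted_toy(n=120, f=4, seed=0, hyperparams=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, f))
    y = ((X[:, 0] + 0.6 * X[:, 1] + rng.normal(scale=0.5, size=n)) > 0).astype(int)
    table = make_toy_table(X)
    hp = hyperparams or {"n_estimators": 3, "max_depth": 3}
    return fit_tissue_model(table, y, "heart", hp, seed), table


class TestShapExplain:
    def test_local_accuracy_against_float64_margin(self):
        model, table = fitted_toy(hyperparams={"n_estimators": 60, "max_depth": 4})
        expl = shap_explain(model, table)
        margins = margin_scores(model, table)
        err = np.abs(expl.base_value + expl.values.sum(axis=1) - margins)
        assert err.max() < 1e-6

    def test_matches_powerset_oracle_small_model(self):
        model, table = fitted_toy(f=4, hyperparams={"n_estimators": 3, "max_depth": 2})
        trees = _booster_trees(model, 4)
        expl = shap_explain(model, table)
        X = table.matrix()
        for r in (0, 7, 33):
            phi = oracles.shapley_powerset(trees, X[r], 4)
            assert np.allclose(expl.values[r], phi, atol=1e-9)

    def test_matches_xgboost_builtin_contributions(self):
        import xgboost

        model, table = fitted_toy(hyperparams={"n_estimators": 30, "max_depth": 3})
        expl = shap_explain(model, table)
        contrib = model.booster().predict(
            xgboost.DMatrix(table.matrix()), pred_contribs=True
        )
        assert np.abs(expl.values - contrib[:, :-1]).max() < 1e-4

    def test_constant_model_gives_zero_attributions(self):
        # single-class-like: labels correlated with nothing learnable
        rng = np.random.default_rng(0)
        X = np.zeros((30, 3))
        y = np.array([0, 1] * 15)
        table = make_toy_table(X)
        model = fit_tissue_model(table, y, "heart", {"n_estimators": 2, "max_depth": 1}, 0)
        expl = shap_explain(model, table)
        assert np.allclose(expl.values, 0.0)
        margins = margin_scores(model, table)
        assert np.allclose(expl.base_value, margins, atol=1e-9)


class TestFeatureImportance:
    def test_zero_attribution_feature_has_zero_importance(self):
        model, table = fitted_toy()
        expl = shap_explain(model, table)
        dead = [j for j, name in enumerate(expl.feature_names) if np.allclose(expl.values[:, j], 0)]
        imp = feature_importance(expl)
        for j in dead:
            assert imp.iloc[j] == 0.0

    def test_median_of_absolute_values(self):
        from tracevar.interpretation import ShapExplanation

        expl = ShapExplanation(["a", "b", "c"], ["f0"], np.array([[-3.0], [1.0], [5.0]]), 0.0)
        assert feature_importance(expl)["f0"] == 3.0
        assert feature_importance(expl, mode="signed")["f0"] == 1.0

    def test_order_invariance(self):
        model, table = fitted_toy(seed=5)
        expl = shap_explain(model, table)
        imp1 = feature_importance(expl)
        perm = np.random.default_rng(0).permutation(len(expl.variant_ids))
        expl.values = expl.values[perm]
        expl.variant_ids = [expl.variant_ids[i] for i in perm]
        imp2 = feature_importance(expl)
        pd.testing.assert_series_equal(imp1, imp2)


class TestPartition:
    def test_worked_example_modeled_vs_other(self):
        meta = schema.default_feature_meta()
        parts = partition_features(meta, "skeletal_muscle")
        assert "expression_1__skeletal_muscle" in parts["modeled_tissue"]
        assert "expression_1__liver" in parts["other_tissue"]

    def test_heart_partition_sizes(self):
        meta = schema.default_feature_meta()
        parts = partition_features(meta, "heart")
        assert (len(parts["variant"]), len(parts["modeled_tissue"]), len(parts["other_tissue"])) == (84, 36, 459)

    def test_whole_brain_partition_sizes(self):
        meta = schema.default_feature_meta()
        parts = partition_features(meta, "whole_brain")
        assert (len(parts["variant"]), len(parts["modeled_tissue"]), len(parts["other_tissue"])) == (84, 102, 393)

    def test_unknown_tissue_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            partition_features(schema.default_feature_meta(), "spleen")


class TestGroupImportance:
    def _importances(self, meta, hot=()):
        vals = pd.Series(0.01, index=[m.name for m in meta])
        for h in hot:
            vals[h] = 1.0
        return vals

    def test_normalized_contributions_sum_to_one(self):
        meta = schema.default_feature_meta()
        gi = group_importance(self._importances(meta), meta, "heart")
        assert gi.normalized.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_group_has_zero_value(self):
        meta = schema.default_feature_meta()
        imp = self._importances(meta)
        imp[[m.name for m in meta if m.subgroup == "eqtl"]] = 0.0
        gi = group_importance(imp, meta, "heart")
        eqtl_rows = gi.table[gi.table["group"] == "eqtl"]
        assert (eqtl_rows["value"] == 0).all()

    def test_ppi_subgroups_are_merged(self):
        meta = schema.default_feature_meta()
        gi = group_importance(self._importances(meta), meta, "heart")
        assert "ppi" in set(gi.table["group"])
        assert "differential_ppi" not in set(gi.table["group"])
        assert "elevated_ppi" not in set(gi.table["group"])

    def test_hand_computed_six_feature_toy(self):
        meta = [
            FeatureMeta("a", "variant", "gv", "gv"),
            FeatureMeta("b", "variant", "gv", "gv"),
            FeatureMeta("c__heart", "tissue", "expression", "expression", "heart"),
            FeatureMeta("d__heart", "tissue", "expression", "expression", "heart"),
            FeatureMeta("e__liver", "tissue", "expression", "expression", "liver"),
            FeatureMeta("f__liver", "tissue", "expression", "expression", "liver"),
        ]
        imp = pd.Series({"a": 4.0, "b": 2.0, "c__heart": 2.0, "d__heart": 1.0, "e__liver": 1.0, "f__liver": 0.0})
        gi = group_importance(imp, meta, "heart")
        tab = gi.table.set_index(["group", "partition"])["value"]
        assert tab[("gv", "variant")] == pytest.approx((0.4 + 0.2) / 2)
        assert tab[("expression", "modeled_tissue")] == pytest.approx((0.2 + 0.1) / 2)
        assert tab[("expression", "other_tissue")] == pytest.approx(0.05)

    def test_zero_total_importance_raises(self):
        meta = schema.default_feature_meta()
        with pytest.raises(ValueError, match="zero"):
            group_importance(pd.Series(0.0, index=[m.name for m in meta]), meta, "heart")


class TestRankFeatureClasses:
    def test_equal_importances_give_equal_ranks_and_null_p(self):
        meta = schema.default_feature_meta()
        imp = pd.Series(0.5, index=[m.name for m in meta])
        parts = partition_features(meta, "heart")
        out = rank_feature_classes(imp, parts)
        assert len(set(out["median_rank"].values())) == 1
        assert 0.4 < out["p_modeled_vs_variant"] < 0.6

    def test_planted_modeled_signal_ranks_best(self):
        meta = schema.default_feature_meta()
        rng = np.random.default_rng(0)
        imp = pd.Series(rng.uniform(0, 0.01, size=len(meta)), index=[m.name for m in meta])
        parts = partition_features(meta, "heart")
        imp[parts["modeled_tissue"]] += 1.0
        out = rank_feature_classes(imp, parts)
        assert out["median_rank"]["modeled_tissue"] < out["median_rank"]["variant"]
        assert out["p_adj_modeled_vs_other"] < 1e-6

    def test_ranks_cover_all_features(self):
        meta = schema.default_feature_meta()
        rng = np.random.default_rng(1)
        imp = pd.Series(rng.uniform(size=len(meta)), index=[m.name for m in meta])
        out = rank_feature_classes(imp, partition_features(meta, "heart"))
        assert len(out["ranks"]) == len(meta)
        assert sorted(out["ranks"]) == list(range(1, len(meta) + 1))

    def test_collective_mode_uses_paired_wilcoxon(self):
        med = pd.DataFrame(
            {"variant": [200.0, 210, 190, 220, 205, 215], "modeled_tissue": [100.0, 90, 110, 95, 105, 85],
             "other_tissue": [300.0, 310, 290, 305, 295, 315]}
        )
        out = rank_feature_classes_collective(med)
        assert out["p_modeled_vs_variant"] == pytest.approx(1 / 64)
        assert out["p_modeled_vs_other"] == pytest.approx(1 / 64)

    def test_empty_partition_raises(self):
        meta = schema.default_feature_meta()
        imp = pd.Series(1.0, index=[m.name for m in meta])
        parts = partition_features(meta, "heart")
        parts["modeled_tissue"] = []
        with pytest.raises(ValueError, match="empty"):
            rank_feature_classes(imp, parts)


class TestExplainVariant:
    def test_full_ordering_is_permutation(self):
        model, table = fitted_toy()
        vid = table.variant_ids[0]
        rep = explain_variant(model, table, vid, top_k=len(table.meta))
        assert sorted(rep["feature"]) == sorted(table.feature_names)
        assert (rep["attribution"].abs().diff().dropna() <= 1e-12).all()

    def test_rerun_is_stable(self):
        model, table = fitted_toy(seed=2)
        vid = table.variant_ids[3]
        r1 = explain_variant(model, table, vid, top_k=3)
        r2 = explain_variant(model, table, vid, top_k=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_bad_top_k_raises(self):
        model, table = fitted_toy()
        with pytest.raises(ValueError):
            explain_variant(model, table, table.variant_ids[0], top_k=0)

    def test_planted_tissue_feature_surfaces_in_top_five(self):
        # a muscle-disease-like case: signal planted in the modeled tissue's
        # preferential expression features should appear among the top
        # contributors for a pathogenic variant
        cfg = SimConfig(
            n_genes=100, n_variants=900,
            tissues=("skeletal_muscle", "heart", "liver", "skin", "lung", "whole_blood"),
            tissue_effect={"preferential_expression": 2.5},
            variant_effect=0.4,
            seed=13,
        )
        sim = generate_dataset(cfg)
        features = impute_missing(sim.features)
        y = sim.labels.column("skeletal_muscle")
        model = fit_tissue_model(features, y, "skeletal_muscle", {"n_estimators": 60}, 1)
        path_ids = [v for v, l in zip(features.variant_ids, y) if l == 1]
        hits = 0
        for vid in path_ids[:6]:
            rep = explain_variant(model, features, vid, top_k=5)
            if any(
                rep["subgroup"].iloc[i] == "preferential_expression"
                and rep["tissue_tag"].iloc[i] == "skeletal_muscle"
                for i in range(len(rep))
            ):
                hits += 1
        assert hits >= 4
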