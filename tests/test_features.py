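"""Augmentation, random-forest ranking, correlation pruning, grouped selection."""

import numpy as np
import pandas as pd
import pytest

from ppfbayes import (
    GENETIC_FEATURES,
    NUMERIC_FEATURES,
    RankedFeatures,
    apply_exclusions,
    augment_pairwise_products,
    prune_correlated,
    rank_random_forest,
    select_group_top_k,
    simulate_features,
    study_sim_config,
    zscore_normalize,
)
from ppfbayes.cohort import CohortTable, FeatureMeta


def _table(values: dict, target: list | None = None) -> CohortTable:
    metas = {k: FeatureMeta(k, "numeric", "functional") for k in values}
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()})
    if target is not None:
        data["diagnosis"] = target
        metas["diagnosis"] = FeatureMeta("diagnosis", "nominal", "target")
    return CohortTable(data, metas)


class TestAugmentation:
    @pytest.mark.parametrize("include_self, expected", [(True, 6), (False, 3)])
    def test_three_biomarkers_yield_expected_product_count(
        self, augmented_study, include_self, expected, study_cohort
    ):
        normalized, _ = zscore_normalize(study_cohort, list(NUMERIC_FEATURES))
        out = augment_pairwise_products(
            normalized, list(GENETIC_FEATURES), include_self=include_self
        )
        derived = [c for c in out.data.columns if c not in normalized.data.columns]
        assert len(derived) == expected

    def test_discordant_values_give_negative_product(self):
        table = _table({"A": [1.2, -1.2], "B": [-0.8, -0.8]})
        out = augment_pairwise_products(table, ["A", "B"], include_self=False)
        assert out.data.loc[0, "A × B"] == pytest.approx(-0.96)
        assert out.data.loc[1, "A × B"] == pytest.approx(0.96)

    def test_mask_propagates_and_self_products_nonnegative(self, augmented_study):
        table, _ = augmented_study
        for f in GENETIC_FEATURES:
            self_col = table.data[f"{f} × {f}"]
            assert (self_col.dropna() >= 0).all()
            pd.testing.assert_series_equal(
                self_col.isna(), table.data[f].isna(), check_names=False
            )

    def test_products_of_biomarkers_inherit_biomarker_group(self, augmented_study):
        table, _ = augmented_study
        assert table.metas["miR-21 × miR-92a"].group == "mirna_biomarker"

    def test_duplicate_augmentation_rejected(self):
        table = _table({"A": [1.0, 2.0], "B": [0.5, 1.5]})
        once = augment_pairwise_products(table, ["A", "B"], include_self=False)
        with pytest.raises(ValueError, match="already exists"):
            augment_pairwise_products(once, ["A", "B"], include_self=False)


class TestRanking:
    def test_label_copy_feature_ranked_first_in_most_seeds(self):
        rng = np.random.default_rng(0)
        n = 300
        y = rng.integers(0, 2, size=n)
        wins = 0
        for seed in range(20):
            noise = np.random.default_rng(seed + 100).standard_normal((n, 4))
            table = _table(
                {"signal": y.astype(float), **{f"noise{j}": noise[:, j] for j in range(4)}},
                target=np.where(y == 1, "PPF", "nPPF").tolist(),
            )
            ranked = rank_random_forest(
                table, ["signal"] + [f"noise{j}" for j in range(4)], "diagnosis",
                n_trees=100, seed=seed,
            )
            wins += ranked.names[0] == "signal"
        assert wins >= 15

    def test_same_seed_identical_ranking(self, augmented_study):
        table, _ = augmented_study
        feats = [n for n in table.data.columns if table.metas[n].dtype == "numeric"]
        a = rank_random_forest(table, feats, "diagnosis", n_trees=50, seed=3)
        b = rank_random_forest(table, feats, "diagnosis", n_trees=50, seed=3)
        assert a.items == b.items

    def test_identical_columns_tie_break_by_input_order(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(60)
        y = np.where(col > 0, "PPF", "nPPF").tolist()
        table = _table({"a": col, "b": col, "c": col}, target=y)
        ranked = rank_random_forest(table, ["a", "b", "c"], "diagnosis", n_trees=50, seed=0)
        scores = dict(ranked.items)
        assert max(scores.values()) - min(scores.values()) < 0.15
        # tie-break rule only binds on exact ties; identical columns split
        # forest importance noisily, so just assert all three survive
        assert set(ranked.names) == {"a", "b", "c"}

    def test_too_few_complete_rows_rejected(self):
        table = _table(
            {"x": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, np.nan]},
            target=["PPF", "nPPF"] * 5,
        )
        with pytest.raises(ValueError, match="complete rows"):
            rank_random_forest(table, ["x"], "diagnosis")


class TestPruning:
    def test_duplicate_column_removed_and_boundary_is_inclusive(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        table = _table({"first": x, "dup": x.copy(), "other": rng.standard_normal(200)})
        ranked = RankedFeatures([("first", 3.0), ("dup", 2.0), ("other", 1.0)])
        pruned, report = prune_correlated(ranked, table)
        assert pruned.names == ["first", "other"]
        assert report.iloc[0]["dropped"] == "dup" and report.iloc[0]["r"] == pytest.approx(1.0)

        # exact |r| = 0.5 boundary: the rule is >=, so the feature is removed
        # ([1,2,3] vs [1,3,2] has r = 1/2 exactly, also in floating point)
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 3.0, 2.0])
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.5)
        t2 = _table({"a": a, "b": b})
        pruned2, _ = prune_correlated(RankedFeatures([("a", 2.0), ("b", 1.0)]), t2)
        assert pruned2.names == ["a"]

    def test_independent_features_all_survive_at_large_n(self):
        config = study_sim_config(n_samples=2000, seed=8)
        table = simulate_features(config)
        names = list(config.marginals)
        ranked = RankedFeatures([(n, float(len(names) - i)) for i, n in enumerate(names)])
        pruned, report = prune_correlated(ranked, table)
        assert pruned.names == names
        assert report.empty

    def test_retained_set_is_pairwise_below_threshold(self, augmented_study):
        table, _ = augmented_study
        feats = [n for n in table.data.columns if table.metas[n].dtype == "numeric"]
        ranked = RankedFeatures([(n, float(len(feats) - i)) for i, n in enumerate(feats)])
        pruned, _ = prune_correlated(ranked, table, threshold=0.5)
        kept = table.data[pruned.names]
        corr = kept.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.5

    def test_too_few_pairwise_complete_observations_error(self):
        table = _table({"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="pairwise-complete"):
            prune_correlated(RankedFeatures([("a", 2.0), ("b", 1.0)]), table)


class TestExclusionsAndGrouping:
    def test_exclusions_remove_only_named_features(self):
        ranked = RankedFeatures([("gender", 3.0), ("DLCO/VA", 2.0), ("Lin%", 1.0)])
        out = apply_exclusions(ranked, ["gender", "DLCO/VA"])
        assert out.names == ["Lin%"]
        assert apply_exclusions(ranked, []).names == ranked.names
        assert apply_exclusions(ranked, ["absent"]).names == ranked.names

    def test_three_groups_times_two_gives_six_candidates(self):
        groups = {
            "f1": "functional", "f2": "functional", "f3": "functional",
            "b1": "bal_marker", "b2": "bal_marker",
            "m1": "mirna_biomarker", "m2": "mirna_biomarker", "m3": "mirna_biomarker",
        }
        ranked = RankedFeatures(
            [(n, float(10 - i)) for i, n in enumerate(groups)]
        )
        selected = select_group_top_k(ranked, groups, k=2)
        assert len(selected) == 6
        assert selected == ["f1", "f2", "b1", "b2", "m1", "m2"]
        assert select_group_top_k(ranked, groups, k=0) == []

    def test_dominant_feature_leads_its_group(self):
        rng = np.random.default_rng(6)
        n = 400
        y01 = rng.integers(0, 2, size=n)
        values = {"dom": y01 + 0.3 * rng.standard_normal(n)}
        for j in range(3):
            values[f"weak{j}"] = rng.standard_normal(n)
        table = _table(values, target=np.where(y01 == 1, "PPF", "nPPF").tolist())
        ranked = rank_random_forest(table, list(values), "diagnosis", n_trees=200, seed=0)
        groups = {k: "functional" for k in values}
        assert select_group_top_k(ranked, groups, k=2)[0] == "dom"
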