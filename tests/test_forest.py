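"""Gini forests, OOB accounting and the shadow/rank-sum/chi-square screen."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from pulmotex.forest import (
    build_forest,
    chi_square_group,
    chi_square_statistic,
    gini_and_split,
    oob_error,
    predict_majority,
    screen_features,
    shadow_importance,
    subset_probability,
    wilcoxon_screen,
)
from pulmotex.synthetic import generate_feature_table
from pulmotex.types import FeatureTable


class TestGini:
    def test_balanced_two_class(self):
        g, _ = gini_and_split([5, 5], [5, 0], [0, 5])
        assert g == pytest.approx(0.5)

    def test_pure_node(self):
        g, _ = gini_and_split([10, 0], [5, 0], [5, 0])
        assert g == 0.0

    def test_perfect_split_has_zero_child_impurity(self):
        _, gs = gini_and_split([5, 5], [5, 0], [0, 5])
        assert gs == 0.0

    def test_three_balanced_classes(self):
        g, _ = gini_and_split([1, 1, 1], [1, 0, 0], [0, 1, 1])
        assert g == pytest.approx(2 / 3)

    def test_best_split_matches_threshold_enumeration(self):
        """The weighted-Gini minimiser over all thresholds of a 1-D table
        agrees with an exhaustive enumeration oracle."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.integers(0, 2, 30)
            thresholds = np.unique(x)[:-1]

            def weighted(th):
                left = np.bincount(y[x <= th], minlength=2)
                right = np.bincount(y[x > th], minlength=2)
                return gini_and_split(left + right, left, right)[1]

            oracle = min(weighted(t) for t in thresholds)
            table = FeatureTable(x[:, None], y + 1)
            forest = build_forest(table, K=1, mtry=1, nmin=len(x), rng=1)
            # root-only tree: its split must achieve the oracle impurity
            tree = forest.trees[0]
            xb, yb = x[tree.bag], y[tree.bag]
            if tree.feat[0] >= 0:
                left = np.bincount(yb[xb <= tree.thresh[0]], minlength=2)
                right = np.bincount(yb[xb > tree.thresh[0]], minlength=2)
                got = gini_and_split(left + right, left, right)[1]
                oracle_bag = min(
                    (
                        gini_and_split(
                            np.bincount(yb, minlength=2),
                            np.bincount(yb[xb <= t], minlength=2),
                            np.bincount(yb[xb > t], minlength=2),
                        )[1]
                        for t in np.unique(xb)[:-1]
                    ),
                    default=None,
                )
                assert got == pytest.approx(oracle_bag, abs=1e-12)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            gini_and_split([4, 4], [3, 0], [0, 4])


class TestBuildPredict:
    def test_separable_table_is_memorised(self, label_equals_feature_table):
        forest = build_forest(label_equals_feature_table, K=10, rng=0)
        pred = predict_majority(forest, label_equals_feature_table.features)
        assert np.all(pred == label_equals_feature_table.labels)

    def test_same_seed_same_forest(self, planted_easy):
        f1 = build_forest(planted_easy.table, K=5, rng=42)
        f2 = build_forest(planted_easy.table, K=5, rng=42)
        for t1, t2 in zip(f1.trees, f2.trees):
            assert np.array_equal(t1.feat, t2.feat)
            assert np.array_equal(t1.thresh, t2.thresh)
            assert np.array_equal(t1.bag, t2.bag)

    def test_single_feature_forced_candidate(self):
        rng = np.random.default_rng(1)
        table = FeatureTable(rng.normal(size=(50, 1)), rng.integers(1, 3, 50))
        forest = build_forest(table, K=3, mtry=1, rng=0)
        for tree in forest.trees:
            assert set(tree.feat[tree.feat >= 0]) <= {0}

    def test_mtry_out_of_range_rejected(self, planted_easy):
        with pytest.raises(ValueError):
            build_forest(planted_easy.table, K=2, mtry=99)

    def test_accuracy_comparable_to_sklearn(self, planted_easy):
        """Cross-check against sklearn's forest on the same planted data:
        OOB-style generalization should be in the same band."""
        table = planted_easy.table
        rng = np.random.default_rng(0)
        idx = rng.permutation(table.n_samples)
        tr, te = idx[:150], idx[150:]
        train = FeatureTable(table.features[tr], table.labels[tr])
        ours = build_forest(train, K=50, rng=0)
        ours_acc = np.mean(predict_majority(ours, table.features[te]) == table.labels[te])
        sk = RandomForestClassifier(n_estimators=50, random_state=0).fit(
            table.features[tr], table.labels[tr]
        )
        sk_acc = sk.score(table.features[te], table.labels[te])
        assert abs(ours_acc - sk_acc) < 0.12

    def test_group_stratified_candidates_always_include_strong(self, planted_easy):
        strong = np.array(sorted(planted_easy.informative_indices))
        weak = np.array(sorted(planted_easy.noise_indices))
        forest = build_forest(planted_easy.table, K=10, mtry=4, rng=3,
                              groups=(strong, weak))
        # every split the forest chose used some feature; root splits in a
        # planted table should overwhelmingly use the strong group
        root_feats = [t.feat[0] for t in forest.trees if t.feat[0] >= 0]
        assert any(f in set(strong) for f in root_feats)


class TestOOB:
    def test_single_tree_oob_fraction_near_bootstrap_expectation(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(rng.normal(size=(100, 3)), rng.integers(1, 3, 100))
        fracs = []
        for seed in range(20):
            forest = build_forest(table, K=1, rng=seed)
            oob = 100 - np.unique(forest.trees[0].bag).size
            fracs.append(oob / 100)
        assert np.mean(fracs) == pytest.approx((1 - 1 / 100) ** 100, abs=0.1)

    def test_separable_data_low_oob_error(self, label_equals_feature_table):
        forest = build_forest(label_equals_feature_table, K=50, rng=0)
        err, preds, uncovered = oob_error(forest, label_equals_feature_table)
        assert err < 0.05
        assert uncovered < 5

    def test_oob_error_tracks_effect_size(self):
        for seed in range(3):
            strong = generate_feature_table(150, 8, 3, 3.0, seed=seed)
            null = generate_feature_table(150, 8, 3, 0.0, seed=seed)
            e_strong = oob_error(build_forest(strong.table, K=60, rng=seed), strong.table)[0]
            e_null = oob_error(build_forest(null.table, K=60, rng=seed), null.table)[0]
            assert e_strong < e_null

    def test_empty_forest_rejected(self, planted_easy):
        forest = build_forest(planted_easy.table, K=1, rng=0)
        forest.trees = []
        with pytest.raises(ValueError):
            oob_error(forest, planted_easy.table)


class TestShadowScreen:
    def test_separable_feature_beats_shadows_every_replicate(
        self, label_equals_feature_table
    ):
        scores, shadow_max = shadow_importance(
            label_equals_feature_table, R=10, K=25, rng=0
        )
        assert np.all(scores[:, 0] > shadow_max)

    def test_minimal_rank_sum_pvalue(self):
        """All 10 feature scores above all 10 shadow scores gives the
        extreme one-sided rank-sum p-value 1/C(20,10)."""
        scores = np.linspace(1.0, 2.0, 10)[:, None]
        shadows = np.linspace(0.0, 0.5, 10)
        kept, pvals = wilcoxon_screen(scores, shadows, theta=0.05)
        assert kept.tolist() == [0]
        assert pvals[0] == pytest.approx(1 / 184756, rel=1e-6)

    def test_zero_theta_keeps_nothing(self):
        rng = np.random.default_rng(0)
        kept, _ = wilcoxon_screen(rng.normal(size=(8, 4)), rng.normal(size=8), theta=0.0)
        assert kept.size == 0

    def test_replicate_floor_enforced(self, planted_easy):
        with pytest.raises(ValueError):
            shadow_importance(planted_easy.table, R=3)

    def test_fixed_seed_reproducible(self, planted_easy):
        s1, m1 = shadow_importance(planted_easy.table, R=5, K=10, rng=7)
        s2, m2 = shadow_importance(planted_easy.table, R=5, K=10, rng=7)
        assert np.array_equal(s1, s2) and np.array_equal(m1, m2)

    def test_full_screen_recovers_planted_features(self):
        """The full shadow -> rank-sum pipeline keeps most planted
        features and few noise features."""
        hits = 0
        for seed in range(3):
            pt = generate_feature_table(300, 20, 4, 2.0, seed=200 + seed)
            report = screen_features(pt.table, R=10, K=30, rng=seed)
            kept = set(report.kept.tolist())
            n_planted = len(kept & pt.informative_indices)
            n_noise = len(kept & pt.noise_indices)
            if n_planted >= 3 and n_noise <= 2:
                hits += 1
        assert hits >= 2


class TestChiSquare:
    def test_independent_table_statistic_zero(self):
        assert chi_square_statistic([[10, 10], [10, 10]]) == 0.0

    def test_perfectly_dependent_table(self):
        assert chi_square_statistic([[20, 0], [0, 20]]) == pytest.approx(40.0)

    def test_independent_feature_lands_weak(self):
        """A label-independent feature should fall in the weak group in
        most seeds (chi-square calibration)."""
        weak_hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = np.tile([1, 2, 3], 50)
            X = rng.normal(size=(150, 1))
            table = FeatureTable(X, labels)
            ys, yw = chi_square_group(table, np.array([0]), bins=4, alpha2=0.05)
            weak_hits += int(0 in yw)
        assert weak_hits >= 9

    def test_dependent_feature_lands_strong(self):
        rng = np.random.default_rng(0)
        labels = np.tile([1, 2, 3], 50)
        X = labels[:, None] + rng.normal(0, 0.3, (150, 1))
        ys, _ = chi_square_group(FeatureTable(X, labels), np.array([0]))
        assert 0 in ys


class TestSubsetProbability:
    def test_worked_combinatorics(self):
        exact, approx = subset_probability(10, 5, 2)
        assert exact == pytest.approx(10 / 45)
        assert approx == pytest.approx(0.25)

    def test_no_informative_features(self):
        assert subset_probability(10, 0, 3)[0] == 1.0

    def test_full_draw_with_informative(self):
        assert subset_probability(10, 1, 10)[0] == 0.0

    def test_approximation_close_for_small_ratio(self):
        exact, approx = subset_probability(100, 5, 3)
        assert approx == pytest.approx(exact, rel=0.05)
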