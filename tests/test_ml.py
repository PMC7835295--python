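"""Cross-validation pipeline building blocks and leakage/determinism guards."""

import numpy as np
import pytest
from scipy import stats as sps

from psma_radiomics.ml import (
    PipelineConfig,
    RadiomicsForest,
    auc_score,
    brier_score,
    feature_importances,
    reduce_anova_top10,
    reduce_pca95,
    reduce_rfe,
    run_repeated_cv,
    smote_oversample,
    zscore_fit_apply,
)

FAST = PipelineConfig(n_trees=25, repeats=2, outer_folds=3, inner_folds=2,
                      search_iters=1, max_depths=(None,), criteria=("gini",),
                      seed=0)


def informative_data(n=90, d=20, beta=2.0, prevalence=-1.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    X = np.outer(a, rng.standard_normal(d) * 0.6) + rng.standard_normal((n, d))
    p = 1.0 / (1.0 + np.exp(-(beta * a + prevalence)))
    y = (rng.uniform(size=n) < p).astype(int)
    return X, y


class TestZScore:
    def test_train_self_normalised(self, rng):
        X = rng.uniform(1, 5, (30, 6))
        tr, _ = zscore_fit_apply(X, X)
        assert np.allclose(tr.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(tr.std(axis=0), 1, atol=1e-12)

    def test_constant_column_guarded(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        tr, te = zscore_fit_apply(X, X + 1.0)
        assert not np.isnan(tr).any() and not np.isnan(te).any()
        assert np.allclose(tr[:, 0], 0.0)

    def test_test_shift_scales_by_train_sd(self, rng):
        X = rng.normal(5, 3, (50, 1))
        _, te = zscore_fit_apply(X, X + 6.0)
        tr, _ = zscore_fit_apply(X, X)
        assert np.allclose(te - tr, 6.0 / X.std(axis=0), atol=1e-12)


class TestPCA95:
    def test_single_dominant_direction(self, rng):
        base = rng.standard_normal((100, 1)) * 30.0
        X = base @ np.ones((1, 8)) + rng.standard_normal((100, 8)) * 0.1
        _, _, k = reduce_pca95(X, X)
        assert k == 1

    def test_isotropic_noise_needs_most_components(self, rng):
        X = rng.standard_normal((400, 10))
        _, _, k = reduce_pca95(X, X)
        assert k >= 9

    def test_output_dimension_bound(self, rng):
        X = rng.standard_normal((12, 50))
        tr, te, k = reduce_pca95(X, X)
        assert k <= min(11, 50)
        assert tr.shape[1] == k


class TestAnovaTop10:
    def test_480_features_retain_48(self, rng):
        X = rng.standard_normal((60, 480))
        y = rng.integers(0, 2, 60)
        idx = reduce_anova_top10(X, y)
        assert len(idx) == 48

    def test_label_copy_always_retained(self, rng):
        X = rng.standard_normal((50, 20))
        y = rng.integers(0, 2, 50)
        X[:, 7] = y
        idx = reduce_anova_top10(X, y)
        assert 7 in idx

    def test_f_equals_squared_t(self, rng):
        """One-way F with two groups equals the squared pooled-variance t."""
        from sklearn.feature_selection import f_classif

        X = rng.standard_normal((40, 3))
        y = np.array([0] * 18 + [1] * 22)
        F, _ = f_classif(X, y)
        for j in range(3):
            t, _ = sps.ttest_ind(X[y == 0, j], X[y == 1, j])
            assert F[j] == pytest.approx(t**2)


class TestRFE:
    def test_informative_features_recovered(self):
        rng = np.random.default_rng(5)
        n, d_noise = 150, 25
        y = rng.integers(0, 2, n)
        informative = y[:, None] + rng.standard_normal((n, 5)) * 0.4
        X = np.hstack([informative, rng.standard_normal((n, d_noise))])
        kept = reduce_rfe(X, y, seed=3, inner_folds=3, n_trees=40)
        assert len(set(kept) & {0, 1, 2, 3, 4}) >= 3

    def test_single_feature_returned_unchanged(self, rng):
        X = rng.standard_normal((20, 1))
        y = rng.integers(0, 2, 20)
        assert list(reduce_rfe(X, y)) == [0]


class TestSMOTE:
    def test_two_minority_points_interpolate_on_segment(self, rng):
        Xmaj = rng.normal(10, 1, (20, 3))
        Xmin = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 4.0]])
        X = np.vstack([Xmaj, Xmin])
        y = np.array([1] * 20 + [0] * 2)
        Xo, yo = smote_oversample(X, y, seed=1)
        assert (yo == 0).sum() == (yo == 1).sum() == 20
        synth = Xo[22:]
        # every synthetic point is a convex combination of the two minority points
        direction = Xmin[1] - Xmin[0]
        for s in synth:
            u = (s - Xmin[0]) / direction
            assert np.allclose(u, u[0])
            assert -1e-9 <= u[0] <= 1 + 1e-9

    def test_minority_mean_approximately_preserved(self):
        devs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Xmin = rng.normal(2.0, 1.0, (10, 4))
            Xmaj = rng.normal(-2.0, 1.0, (50, 4))
            X = np.vstack([Xmaj, Xmin])
            y = np.array([0] * 50 + [1] * 10)
            Xo, yo = smote_oversample(X, y, seed=seed)
            devs.append(np.abs(Xo[yo == 1].mean() - Xmin.mean()))
        assert np.mean(devs) < 0.1 * 2.0

    def test_minority_too_small_rejected(self):
        X = np.ones((5, 2))
        y = np.array([0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="minority"):
            smote_oversample(X, y)


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc_score(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert brier_score(y, y.astype(float)) == 0.0

    def test_uninformative_half_probability(self):
        y = np.array([0, 1, 0, 1])
        assert brier_score(y, np.full(4, 0.5)) == pytest.approx(0.25)

    def test_auc_matches_pair_counting_oracle(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([0.3, 0.6, 0.6, 0.9, 0.2, 0.1])
        pairs, wins = 0, 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                pairs += 1
                wins += 1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
        assert auc_score(y, s) == pytest.approx(wins / pairs)


class TestImportances:
    def test_sum_to_one_and_label_copy_dominates(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        X = rng.standard_normal((80, 10))
        y = rng.integers(0, 2, 80)
        X[:, 4] = y
        f = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        imp = feature_importances(f)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(imp) == 4

    def test_top_percentile_report_size(self, rng):
        X = rng.standard_normal((60, 480))
        y = rng.integers(0, 2, 60)
        model = RadiomicsForest(X, y, PipelineConfig(
            n_trees=30, repeats=1, dim_reduction="anova_top10pct",
            search_iters=1, max_depths=(None,), criteria=("gini",), seed=1))
        full = model.fit_full()
        top = full.top_percentile(10.0)
        assert len(top) == 48
        assert full.importances.sum() == pytest.approx(1.0, abs=1e-9)


class TestRepeatedCV:
    def test_fold_count_and_partition(self):
        X, y = informative_data(n=60, seed=2)
        res = RadiomicsForest(X, y, FAST).fit()
        assert len(res.records) == FAST.repeats * FAST.outer_folds
        for rep in range(FAST.repeats):
            cells = [r for r in res.records if r.repeat == rep]
            all_idx = np.concatenate([r.test_indices for r in cells])
            assert sorted(all_idx) == list(range(60))

    def test_stratification_balanced(self):
        X, y = informative_data(n=61, seed=3)
        res = RadiomicsForest(X, y, FAST).fit()
        for rep in range(FAST.repeats):
            pos = [y[r.test_indices].sum() for r in res.records if r.repeat == rep]
            assert max(pos) - min(pos) <= 1

    def test_same_seed_identical_results(self):
        X, y = informative_data(n=45, seed=4)
        r1 = RadiomicsForest(X, y, FAST).fit()
        r2 = run_repeated_cv(X, y, FAST)
        assert [r.auc for r in r1.records] == [r.auc for r in r2.records]
        for a, b in zip(r1.records, r2.records):
            assert np.array_equal(a.y_prob, b.y_prob)

    def test_test_labels_never_touch_the_fit(self):
        """Scrambling held-out labels leaves the held-out predictions unchanged."""
        X, y = informative_data(n=45, seed=5)
        model = RadiomicsForest(X, y, FAST)
        train_idx = np.arange(30)
        test_idx = np.arange(30, 45)
        rec1 = model._fit_one_fold(train_idx, test_idx, np.random.default_rng(9))
        y2 = y.copy()
        y2[test_idx] = np.random.default_rng(0).permutation(y2[test_idx])
        model2 = RadiomicsForest(X, y2, FAST)
        rec2 = model2._fit_one_fold(train_idx, test_idx, np.random.default_rng(9))
        assert np.array_equal(rec1.y_prob, rec2.y_prob)

    def test_signal_beats_null(self):
        Xs, ys = informative_data(n=80, beta=3.0, seed=6)
        Xn, yn = informative_data(n=80, beta=0.0, seed=6)
        res_s = RadiomicsForest(Xs, ys, FAST).fit()
        res_n = RadiomicsForest(Xn, yn, FAST).fit()
        assert res_s.mean_auc > res_n.mean_auc
        assert res_s.mean_auc > 0.7
        assert 0.3 < res_n.mean_auc < 0.7

    def test_too_few_positives_raises_with_endpoint_name(self):
        X = np.random.default_rng(0).standard_normal((20, 4))
        y = np.array([1, 1] + [0] * 18)
        with pytest.raises(ValueError, match="LNI"):
            RadiomicsForest(X, y, FAST, endpoint="LNI")

    def test_smote_and_reductions_run_inside_cv(self):
        X, y = informative_data(n=66, beta=2.0, prevalence=-1.5, seed=7)
        for dimred in ("pca95", "anova_top10pct"):
            cfg = PipelineConfig(n_trees=20, repeats=1, outer_folds=3,
                                 inner_folds=2, search_iters=1,
                                 max_depths=(None,), criteria=("gini",),
                                 dim_reduction=dimred, oversample="smote", seed=2)
            res = RadiomicsForest(X, y, cfg).fit()
            assert len(res.aucs) >= 1
            assert np.all((res.aucs >= 0) & (res.aucs <= 1))
        if dimred == "pca95":
            assert res.mean_importances() is None

    def test_summary_mentions_key_quantities(self):
        X, y = informative_data(n=45, seed=8)
        res = RadiomicsForest(X, y, FAST, endpoint="GS_ge8").fit()
        text = res.summary()
        assert "GS_ge8" in text and "mean AUC" in text
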