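"""Permutation test, DeLong comparison and ICC agreement oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, pearsonr

from psma_radiomics.ml import PipelineConfig, RadiomicsForest
from psma_radiomics.stats import (
    agreement_sweep,
    delong_test,
    icc_a1,
    icc_category,
    median_delong_compare,
    permutation_test,
)

TINY = PipelineConfig(n_trees=20, repeats=2, outer_folds=3, inner_folds=2,
                      search_iters=1, max_depths=(None,), criteria=("gini",),
                      seed=0)


# ---------------------------------------------------------------------- DeLong


def brute_delong(y, a, b):
    """Structural-component oracle via explicit psi-function double loops."""
    pos_a, neg_a = a[y == 1], a[y == 0]
    pos_b, neg_b = b[y == 1], b[y == 0]
    m, n = len(pos_a), len(neg_a)

    def psi(x, yv):
        return 1.0 if x > yv else 0.5 if x == yv else 0.0

    def components(pos, neg):
        v10 = np.array([np.mean([psi(p, q) for q in neg]) for p in pos])
        v01 = np.array([np.mean([psi(p, q) for p in pos]) for q in neg])
        return v10.mean(), v10, v01

    auc_a, v10_a, v01_a = components(pos_a, neg_a)
    auc_b, v10_b, v01_b = components(pos_b, neg_b)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        return delta, 1.0
    return delta, 2 * norm.sf(abs(delta) / np.sqrt(var))


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([0.2, 0.8, 0.4, 0.7, 0.9, 0.1])
        delta, p = delong_test(y, s, s)
        assert delta == 0.0 and p == 1.0

    def test_matches_structural_component_oracle(self):
        """8-subject toy set: placements match the psi-function computation."""
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        a = np.array([0.9, 0.6, 0.55, 0.5, 0.3, 0.2, 0.65, 0.8])
        b = np.array([0.7, 0.5, 0.8, 0.4, 0.45, 0.3, 0.6, 0.2])
        delta, p = delong_test(y, a, b)
        bd, bp = brute_delong(y, a, b)
        assert delta == pytest.approx(bd)
        assert p == pytest.approx(bp)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_agreement_random(self, seed):
        rng = np.random.default_rng(seed)
        y = np.array([0] * 6 + [1] * 5)
        a = rng.uniform(size=11)
        b = rng.uniform(size=11)
        delta, p = delong_test(y, a, b)
        bd, bp = brute_delong(y, a, b)
        assert delta == pytest.approx(bd) and p == pytest.approx(bp)

    def test_swap_symmetry(self, rng):
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        a, b = rng.uniform(size=20), rng.uniform(size=20)
        d1, p1 = delong_test(y, a, b)
        d2, p2 = delong_test(y, b, a)
        assert d1 == pytest.approx(-d2) and p1 == pytest.approx(p2)


class TestMedianDeLong:
    def test_identical_models_median_p_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        y = (X[:, 0] + rng.standard_normal(40) > 0).astype(int)
        res_a = RadiomicsForest(X, y, TINY).fit()
        res_b = RadiomicsForest(X, y, TINY).fit()  # same seed, same model
        out = median_delong_compare(res_a, res_b)
        assert out["median_p"] == 1.0
        assert out["n_folds_used"] <= TINY.repeats * TINY.outer_folds

    def test_separated_models_detected(self):
        rng = np.random.default_rng(2)
        n = 80
        a = rng.standard_normal(n)
        y = (a + 0.3 * rng.standard_normal(n) > 0).astype(int)
        X_good = np.column_stack([a, rng.standard_normal(n)])
        X_bad = rng.standard_normal((n, 2))
        cfg = PipelineConfig(n_trees=50, repeats=4, outer_folds=4, inner_folds=2,
                             search_iters=1, max_depths=(None,),
                             criteria=("gini",), seed=3)
        res_good = RadiomicsForest(X_good, y, cfg).fit()
        res_bad = RadiomicsForest(X_bad, y, cfg).fit()
        out = median_delong_compare(res_good, res_bad)
        assert out["median_p"] < 0.2
        assert res_good.mean_auc > res_bad.mean_auc

    def test_mismatched_partitions_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 3))
        y = (X[:, 0] > 0).astype(int)
        res_a = RadiomicsForest(X, y, TINY).fit()
        from dataclasses import replace

        res_b = RadiomicsForest(X, y, replace(TINY, seed=99)).fit()
        with pytest.raises(ValueError, match="partition"):
            median_delong_compare(res_a, res_b)


# ------------------------------------------------------------------------- ICC


def brute_icc(table):
    """Hand two-way ANOVA: mean squares from explicit sums of squares."""
    x = np.asarray(table, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestICC:
    def test_identical_columns_unity(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_a1(x) == pytest.approx(1.0)

    def test_constant_offset_penalised(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.column_stack([base, base + 2.0])
        assert icc_a1(x) < 1.0
        assert icc_a1(x) > 0.0

    def test_matches_hand_anova_oracle(self):
        x = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0], [7.0, 6.0]])
        assert icc_a1(x) == pytest.approx(brute_icc(x))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin(self, seed):
        """Independent oracle: pingouin's ICC2 (absolute agreement, single)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        base = rng.normal(5, 2, 12)
        x = np.column_stack([base + rng.normal(0, 1, 12),
                             base + rng.normal(0, 1, 12)])
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "value": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="value")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_a1(x) == pytest.approx(icc2, abs=1e-9)

    def test_reorder_invariance_and_pearson_limit(self, rng):
        base = rng.normal(0, 1, 20)
        x = np.column_stack([base + rng.normal(0, 0.3, 20),
                             base + rng.normal(0, 0.3, 20)])
        perm = rng.permutation(20)
        assert icc_a1(x[perm]) == pytest.approx(icc_a1(x))
        # equal means/variances: ICC approaches Pearson r
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        r = pearsonr(z[:, 0], z[:, 1]).statistic
        assert icc_a1(z) == pytest.approx(r, abs=0.05)

    def test_category_boundaries_go_up(self):
        assert icc_category(0.49) == "poor"
        assert icc_category(0.5) == "moderate"
        assert icc_category(0.75) == "good"
        assert icc_category(0.9) == "excellent"
        assert icc_category(float("nan")) == "undefined"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_a1(np.ones((2, 2)))


class TestAgreementSweep:
    def _tables(self, rng, perturb_morph=0.0):
        subjects = [f"S{i}" for i in range(12)]
        base = pd.DataFrame(
            rng.normal(5, 2, (12, 4)),
            index=subjects,
            columns=["stat_mean", "morph_sphericity", "glcm_contrast_3d_mrg",
                     "suv_mean"],
        )
        tables = {}
        for f in (0.5, 0.7):
            for pvc in (False, True):
                t = base.copy()
                if perturb_morph and f == 0.7:
                    t["morph_sphericity"] += rng.normal(0, perturb_morph, 12)
                tables[(f, pvc)] = t
        return tables

    def test_self_comparison_all_excellent(self, rng):
        out = agreement_sweep(self._tables(rng))
        assert np.allclose(out["icc"], 1.0)
        assert (out["category"] == "excellent").all()

    def test_threshold_perturbation_degrades_morphology(self, rng):
        out = agreement_sweep(self._tables(rng, perturb_morph=5.0))
        thr = out[out["comparison"].str.contains("0.50_vs_0.70")]
        morph = thr[thr["feature"] == "morph_sphericity"]["icc"]
        other = thr[thr["feature"] == "stat_mean"]["icc"]
        assert (morph < 0.75).all()
        assert (other > 0.99).all()


# ------------------------------------------------------------------ permutation


class TestPermutation:
    def test_separable_data_p_zero(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 15)
        X = np.column_stack([y + rng.normal(0, 0.05, 30),
                             rng.standard_normal(30)])
        out = permutation_test(X, y, TINY, n_perm=20, perm_repeats=1, seed=1)
        assert out.actual_mean_auc > 0.95
        assert out.p_value == 0.0

    def test_p_granularity(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((24, 3))
        y = np.array([0, 1] * 12)
        out = permutation_test(X, y, TINY, n_perm=10, perm_repeats=1, seed=2)
        assert out.p_value * 10 == pytest.approx(round(out.p_value * 10))
        assert len(out.perm_mean_aucs) == 10
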