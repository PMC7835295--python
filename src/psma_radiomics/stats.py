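"""Inference: permutation significance, DeLong comparison, ICC agreement.

* :func:`permutation_test` — the cross-validated-AUC permutation test:
  labels are shuffled, the full pipeline re-run (10 times repeated 5-fold
  by default), and the p value is the plain fraction of permutation mean
  AUCs at or above the actual mean AUC (granularity 1/n_perm, minimum 0).
* :func:`delong_test` / :func:`median_delong_compare` — paired DeLong test
  on a shared test set via placement values, applied per cross-validation
  fold with the median p over fold cells reported.
* :func:`icc_a1` / :func:`agreement_sweep` — intraclass correlation
  (two-way mixed model, absolute agreement, single measurement) per
  radiomic feature between image variants and delineation thresholds,
  categorised at 0.5 / 0.75 / 0.9 (boundary values go to the higher
  category).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .ml import CVResults, PipelineConfig, RadiomicsForest

__all__ = [
    "PermutationResult",
    "permutation_test",
    "delong_test",
    "median_delong_compare",
    "icc_a1",
    "icc_category",
    "agreement_sweep",
]


# ------------------------------------------------------------------ permutation


@dataclass
class PermutationResult:
    actual_mean_auc: float
    perm_mean_aucs: np.ndarray
    p_value: float


def permutation_test(
    features,
    labels,
    config: PipelineConfig | None = None,
    n_perm: int = 100,
    perm_repeats: int = 10,
    seed: int = 0,
    actual_result: CVResults | None = None,
) -> PermutationResult:
    """Permutation significance of the cross-validated mean AUC.

    The actual mean AUC comes from the pipeline under ``config`` (or from a
    pre-computed ``actual_result``).  Each of ``n_perm`` permutations
    shuffles the labels once and re-runs the same pipeline at
    ``perm_repeats`` repeats; ``p = #{perm mean AUC >= actual} / n_perm``.
    """
    config = config if config is not None else PipelineConfig()
    labels = np.asarray(labels, dtype=int)
    if actual_result is None:
        actual_result = RadiomicsForest(features, labels, config=config).fit()
    actual = actual_result.mean_auc

    rng = np.random.default_rng(seed)
    perm_config = replace(config, repeats=perm_repeats)
    perm_means = []
    for _ in range(n_perm):
        shuffled = rng.permutation(labels)
        res = RadiomicsForest(
            features, shuffled,
            config=replace(perm_config, seed=int(rng.integers(2**31 - 1))),
        ).fit()
        perm_means.append(res.mean_auc)
    perm_means = np.asarray(perm_means)
    p = float((perm_means >= actual).mean())
    return PermutationResult(actual, perm_means, p)


# ---------------------------------------------------------------------- DeLong


def _placements(y: np.ndarray, scores: np.ndarray):
    """Structural components (placement values) of the AUC estimator."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    ranks_all = rankdata(np.concatenate([pos, neg]))
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n  # per positive subject
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m  # per negative subject
    auc = v10.mean()
    return auc, v10, v01


def delong_test(labels, scores_a, scores_b) -> tuple[float, float]:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    Returns ``(delta_auc, p)`` with a two-sided normal p value for
    AUC_A - AUC_B.  Zero estimated variance (e.g. identical score vectors)
    yields p = 1.
    """
    y = np.asarray(labels, dtype=int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len({len(y), len(a), len(b)}) != 1:
        raise ValueError("labels and both score vectors must be aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _placements(y, a)
    auc_b, v10_b, v01_b = _placements(y, b)
    m, n = len(v10_a), len(v01_a)
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, 1.0
    z = delta / np.sqrt(var)
    return delta, float(2.0 * norm.sf(abs(z)))


def median_delong_compare(results_a: CVResults, results_b: CVResults) -> dict:
    """Fold-wise DeLong comparison of two cross-validated models.

    Both results must come from the same partition (same subjects held out
    per fold cell, guaranteed by sharing the pipeline seed).  Fold cells
    lacking both classes are skipped; the median p over the remaining cells
    is the reported comparison p value.
    """
    folds_a = results_a.fold_predictions()
    folds_b = results_b.fold_predictions()
    if len(folds_a) != len(folds_b):
        raise ValueError("fold structures differ between models")
    pvals = []
    for (idx_a, ya, pa), (idx_b, yb, pb) in zip(folds_a, folds_b):
        if not np.array_equal(idx_a, idx_b):
            raise ValueError("test partitions differ; fit both models with the same seed")
        if len(np.unique(ya)) < 2:
            continue
        _, p = delong_test(ya, pa, pb)
        pvals.append(p)
    if not pvals:
        raise ValueError("no fold cell contained both classes")
    return {
        "median_p": float(np.median(pvals)),
        "n_folds_used": len(pvals),
        "fold_p_values": np.asarray(pvals),
    }


# ------------------------------------------------------------------------- ICC


def icc_a1(table: np.ndarray) -> float:
    """ICC, two-way mixed model, absolute agreement, single measurement.

    From the two-way ANOVA mean squares of an (n subjects x k conditions)
    table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Degenerate tables (zero between-subject variance) return NaN.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_category(icc: float) -> str:
    """Categorise an ICC value; boundary values go to the higher category."""
    if np.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def agreement_sweep(
    tables: dict[tuple[float, bool], pd.DataFrame],
    feature_columns=None,
) -> pd.DataFrame:
    """Per-feature ICC between image variants and delineation thresholds.

    ``tables`` maps ``(threshold_fraction, pvc_flag)`` to a feature table
    (subjects x features, matched indices).  Two comparison axes are
    evaluated: original versus PVC at each threshold, and every threshold
    pair within each image variant.  Returns a tidy frame with columns
    ``feature, comparison, icc, category``.
    """
    fractions = sorted({f for f, _ in tables})
    variants = sorted({p for _, p in tables})
    first = next(iter(tables.values()))
    if feature_columns is None:
        feature_columns = [c for c in first.columns
                           if pd.api.types.is_numeric_dtype(first[c])]

    def compare(t1: pd.DataFrame, t2: pd.DataFrame, tag: str, rows: list):
        common = t1.index.intersection(t2.index)
        for feat in feature_columns:
            pair = np.column_stack([
                t1.loc[common, feat].to_numpy(dtype=float),
                t2.loc[common, feat].to_numpy(dtype=float),
            ])
            if np.allclose(pair.std(axis=0), 0):
                icc = 1.0 if np.allclose(pair[:, 0], pair[:, 1]) else float("nan")
            else:
                icc = icc_a1(pair)
            rows.append(
                {"feature": feat, "comparison": tag, "icc": icc,
                 "category": icc_category(icc)}
            )

    rows: list[dict] = []
    if False in variants and True in variants:
        for f in fractions:
            if (f, False) in tables and (f, True) in tables:
                compare(tables[(f, False)], tables[(f, True)],
                        f"orig_vs_pvc@{f:.2f}", rows)
    for pvc in variants:
        for f1, f2 in combinations(fractions, 2):
            if (f1, pvc) in tables and (f2, pvc) in tables:
                tag = f"{f1:.2f}_vs_{f2:.2f}@{'pvc' if pvc else 'orig'}"
                compare(tables[(f1, pvc)], tables[(f2, pvc)], tag, rows)
    return pd.DataFrame(rows)
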