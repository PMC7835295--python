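"""Leakage-safe repeated nested cross-validated random-forest prediction.

The modelling core follows a Model/Results layout: :class:`RadiomicsForest`
is built from a feature matrix and binary endpoint (or from a feature table
via :meth:`RadiomicsForest.from_dataframe`); :meth:`RadiomicsForest.fit`
runs repeated stratified nested cross-validation and returns a
:class:`CVResults` object carrying per-fold out-of-sample predictions,
AUCs, Brier scores, aggregated feature importances and a ``summary()``
table.

Within every training fold, and only there: z-score scaling, dimension
reduction (none / PCA at 95% explained variance / recursive feature
elimination / ANOVA top-10-percentile), SMOTE minority oversampling, and a
randomized hyperparameter search (tree depth, split criterion) in inner
cross-validation.  The held-out fold never enters any fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import brier_score_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PipelineConfig",
    "RadiomicsForest",
    "CVResults",
    "run_repeated_cv",
    "zscore_fit_apply",
    "reduce_pca95",
    "reduce_rfe",
    "reduce_anova_top10",
    "smote_oversample",
    "feature_importances",
    "auc_score",
    "brier_score",
]

DIM_REDUCTIONS = ("none", "pca95", "rfe", "anova_top10pct")


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters of the cross-validation pipeline.

    Defaults follow the reference analysis protocol: a 1000-tree random
    forest evaluated by stratified 5-fold cross-validation repeated 50
    times, with the randomized search drawing 10 candidates over tree
    depth {2, 4, 6, 8, unlimited} and split criterion {gini, entropy}
    scored by AUC in 3-fold inner cross-validation.  Scale ``repeats``,
    ``n_trees`` and ``search_iters`` down for desk-scale experiments.
    """

    n_trees: int = 1000
    outer_folds: int = 5
    repeats: int = 50
    dim_reduction: str = "none"
    oversample: str = "none"
    inner_folds: int = 3
    search_iters: int = 10
    max_depths: tuple = (2, 4, 6, 8, None)
    criteria: tuple = ("gini", "entropy")
    rfe_trees: int = 100
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if self.dim_reduction not in DIM_REDUCTIONS:
            raise ValueError(f"dim_reduction must be one of {DIM_REDUCTIONS}")
        if self.oversample not in ("none", "smote"):
            raise ValueError("oversample must be 'none' or 'smote'")


# ------------------------------------------------------------ building blocks


def zscore_fit_apply(train: np.ndarray, apply_to: np.ndarray):
    """Z-score normalisation fitted on the training block only.

    Columns with zero training standard deviation are scaled with SD 1 so
    constant features map to zeros rather than NaN.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd, (apply_to - mean) / sd


def reduce_pca95(train: np.ndarray, apply_to: np.ndarray, seed: int = 0):
    """PCA retaining 95% of the training variance; components fit on train."""
    n_comp = min(train.shape[0] - 1, train.shape[1])
    if n_comp < 1:
        return train, apply_to, 0
    pca = PCA(n_components=0.95, svd_solver="full")
    tr = pca.fit_transform(train)
    return tr, pca.transform(apply_to), pca.n_components_


def reduce_anova_top10(
    train: np.ndarray, labels: np.ndarray, percentile: float = 10.0
) -> np.ndarray:
    """Indices of features whose ANOVA F reaches the top percentile.

    One-way ANOVA F between the two classes per feature; features with
    F at or above the (100 - percentile)th percentile of the F values are
    retained (48 of 480 at the default 10%).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_classif(train, labels)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    cutoff = np.percentile(F, 100.0 - percentile)
    return np.flatnonzero(F >= cutoff)


def reduce_rfe(
    train: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    inner_folds: int = 3,
    n_trees: int = 100,
    step_fraction: float = 0.1,
) -> np.ndarray:
    """Recursive feature elimination with a random forest, sized by inner CV.

    Features are iteratively pruned by dropping the lowest-importance 10%
    (at least one) per step; every intermediate feature set is scored by
    mean inner-CV AUC and the best-scoring set is returned.  Retained sets
    are nested across steps by construction.
    """
    n_features = train.shape[1]
    if n_features < 2:
        return np.arange(n_features)
    rng = np.random.default_rng(seed)
    active = np.arange(n_features)
    candidates: list[np.ndarray] = []
    while len(active) >= 1:
        candidates.append(active.copy())
        if len(active) == 1:
            break
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
        )
        forest.fit(train[:, active], labels)
        n_drop = max(1, int(np.floor(step_fraction * len(active))))
        order = np.argsort(forest.feature_importances_)
        active = np.sort(active[order[n_drop:]])

    def cv_auc(cols: np.ndarray) -> float:
        skf = StratifiedKFold(
            n_splits=inner_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        aucs = []
        for tr, te in skf.split(train, labels):
            if len(np.unique(labels[te])) < 2:
                continue
            f = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
            )
            f.fit(train[tr][:, cols], labels[tr])
            aucs.append(
                roc_auc_score(labels[te], f.predict_proba(train[te][:, cols])[:, 1])
            )
        return float(np.mean(aucs)) if aucs else 0.5

    scores = [cv_auc(c) for c in candidates]
    return candidates[int(np.argmax(scores))]


def smote_oversample(
    train: np.ndarray, labels: np.ndarray, k: int = 5, seed: int = 0
):
    """SMOTE: synthesise minority samples by interpolating k-NN pairs.

    New samples are ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)`` and
    ``x_nn`` one of the ``k`` nearest minority neighbours of ``x``; the
    minority class is oversampled up to the majority count.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes in the training set")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return train.copy(), labels.copy()
    rng = np.random.default_rng(seed)
    X_min = train[labels == minority]
    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)  # skip self at column 0
    u = rng.uniform(size=(n_new, 1))
    x = X_min[base]
    x_nn = X_min[neigh[base, pick]]
    synthetic = x + u * (x_nn - x)
    X_out = np.vstack([train, synthetic])
    y_out = np.concatenate([labels, np.full(n_new, minority, dtype=labels.dtype)])
    return X_out, y_out


def feature_importances(forest: RandomForestClassifier) -> np.ndarray:
    """Mean-decrease-in-impurity importances, normalised to sum to 1.0."""
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def auc_score(labels, scores) -> float:
    """ROC AUC as the rank statistic (ties count 0.5)."""
    return float(roc_auc_score(labels, scores))


def brier_score(labels, probabilities) -> float:
    """Mean squared difference between predicted probability and outcome."""
    return float(brier_score_loss(labels, probabilities))


# --------------------------------------------------------------------- model


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    test_indices: np.ndarray
    y_true: np.ndarray
    y_prob: np.ndarray
    auc: float  # NaN when the test fold is single-class
    brier: float
    n_features_used: int
    best_params: dict
    importances: np.ndarray | None  # in original feature space; None for PCA


class RadiomicsForest:
    """Random-forest classifier of a binary endpoint from radiomic features.

    Parameters
    ----------
    X
        (n_subjects, n_features) feature matrix.
    y
        Binary labels (0/1).
    config
        Pipeline configuration; defaults to :class:`PipelineConfig`.
    feature_names, endpoint
        Optional labels used in results and summaries.
    """

    def __init__(self, X, y, config: PipelineConfig | None = None,
                 feature_names=None, endpoint: str = "outcome"):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.config = config if config is not None else PipelineConfig()
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(self.X.shape[1])]
        )
        self.endpoint = endpoint
        n_pos = int(self.y.sum())
        n_neg = len(self.y) - n_pos
        if min(n_pos, n_neg) < self.config.outer_folds:
            raise ValueError(
                f"endpoint {endpoint!r}: {min(n_pos, n_neg)} samples in the rarer "
                f"class, fewer than {self.config.outer_folds} folds"
            )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, endpoint: str,
                       feature_columns=None, config: PipelineConfig | None = None):
        """Build from a feature table holding feature columns plus the endpoint."""
        if endpoint not in table.columns:
            raise KeyError(f"endpoint column {endpoint!r} not in table")
        if feature_columns is None:
            feature_columns = [
                c for c in table.columns
                if c != endpoint and pd.api.types.is_numeric_dtype(table[c])
            ]
        X = table[feature_columns].to_numpy(dtype=float)
        y = table[endpoint].to_numpy(dtype=int)
        return cls(X, y, config=config, feature_names=feature_columns,
                   endpoint=endpoint)

    # ------------------------------------------------------------------ fitting
    def _fit_one_fold(self, train_idx, test_idx, rng) -> FoldRecord:
        cfg = self.config
        Xtr, Xte = self.X[train_idx], self.X[test_idx]
        ytr, yte = self.y[train_idx], self.y[test_idx]

        Xtr, Xte = zscore_fit_apply(Xtr, Xte)

        support = None
        if cfg.dim_reduction == "pca95":
            Xtr, Xte, _ = reduce_pca95(Xtr, Xte, seed=int(rng.integers(2**31 - 1)))
        elif cfg.dim_reduction == "rfe":
            support = reduce_rfe(
                Xtr, ytr, seed=int(rng.integers(2**31 - 1)),
                inner_folds=cfg.inner_folds, n_trees=cfg.rfe_trees,
            )
            Xtr, Xte = Xtr[:, support], Xte[:, support]
        elif cfg.dim_reduction == "anova_top10pct":
            support = reduce_anova_top10(Xtr, ytr)
            Xtr, Xte = Xtr[:, support], Xte[:, support]

        best_params = self._search_hyperparameters(Xtr, ytr, rng)

        if cfg.oversample == "smote":
            Xfit, yfit = smote_oversample(
                Xtr, ytr, k=cfg.smote_k, seed=int(rng.integers(2**31 - 1))
            )
        else:
            Xfit, yfit = Xtr, ytr

        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees, random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1, **best_params,
        )
        forest.fit(Xfit, yfit)
        prob = forest.predict_proba(Xte)[:, 1]

        if len(np.unique(yte)) == 2:
            auc = auc_score(yte, prob)
        else:
            auc = float("nan")
        brier = brier_score(yte, prob)

        imp = feature_importances(forest)
        if cfg.dim_reduction == "pca95":
            full_imp = None
        else:
            full_imp = np.zeros(self.X.shape[1])
            cols = support if support is not None else np.arange(self.X.shape[1])
            full_imp[cols] = imp
        return FoldRecord(
            repeat=-1, fold=-1, test_indices=np.asarray(test_idx),
            y_true=yte, y_prob=prob, auc=auc, brier=brier,
            n_features_used=Xtr.shape[1], best_params=best_params,
            importances=full_imp,
        )

    def _search_hyperparameters(self, Xtr, ytr, rng) -> dict:
        """Randomized search over (max depth, criterion) scored by inner-CV AUC."""
        cfg = self.config
        grid = [
            {"max_depth": d, "criterion": c}
            for d in cfg.max_depths for c in cfg.criteria
        ]
        n_draw = min(cfg.search_iters, len(grid))
        if n_draw == 0 or len(grid) == 1:
            return grid[0] if grid else {}
        draws = [grid[i] for i in rng.choice(len(grid), size=n_draw, replace=False)]
        skf = StratifiedKFold(
            n_splits=cfg.inner_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        splits = list(skf.split(Xtr, ytr))
        best, best_score = draws[0], -np.inf
        for params in draws:
            aucs = []
            for tr, te in splits:
                if len(np.unique(ytr[te])) < 2 or len(np.unique(ytr[tr])) < 2:
                    continue
                Xi, yi = Xtr[tr], ytr[tr]
                if cfg.oversample == "smote" and np.bincount(yi).min() >= 2:
                    Xi, yi = smote_oversample(
                        Xi, yi, k=cfg.smote_k, seed=int(rng.integers(2**31 - 1))
                    )
                f = RandomForestClassifier(
                    n_estimators=max(50, cfg.n_trees // 10),
                    random_state=int(rng.integers(2**31 - 1)), n_jobs=1, **params,
                )
                f.fit(Xi, yi)
                aucs.append(roc_auc_score(ytr[te], f.predict_proba(Xtr[te])[:, 1]))
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best_score:
                best, best_score = params, score
        return best

    def fit(self) -> "CVResults":
        """Run the repeated stratified nested cross-validation."""
        cfg = self.config
        records: list[FoldRecord] = []
        ss = np.random.SeedSequence(cfg.seed)
        repeat_seeds = ss.spawn(cfg.repeats)
        for rep, rep_ss in enumerate(repeat_seeds):
            rng = np.random.default_rng(rep_ss)
            skf = StratifiedKFold(
                n_splits=cfg.outer_folds, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            for fold, (tr, te) in enumerate(skf.split(self.X, self.y)):
                rec = self._fit_one_fold(tr, te, rng)
                rec.repeat, rec.fold = rep, fold
                records.append(rec)
        return CVResults(self, records)

    def fit_full(self, rng_seed: int | None = None) -> "FullFitResult":
        """Fit one forest on the entire dataset (for the importance report).

        Scaling, dimension reduction and oversampling follow the pipeline
        configuration but use all subjects; out-of-sample metrics are not
        available from this fit.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)
        X, _ = zscore_fit_apply(self.X, self.X)
        support = np.arange(X.shape[1])
        if cfg.dim_reduction == "pca95":
            raise ValueError("PCA components are not interpretable; "
                             "use a feature-selection reduction for the report")
        if cfg.dim_reduction == "rfe":
            support = reduce_rfe(X, self.y, seed=int(rng.integers(2**31 - 1)),
                                 inner_folds=cfg.inner_folds, n_trees=cfg.rfe_trees)
        elif cfg.dim_reduction == "anova_top10pct":
            support = reduce_anova_top10(X, self.y)
        Xs = X[:, support]
        ys = self.y
        if cfg.oversample == "smote":
            Xs, ys = smote_oversample(Xs, ys, k=cfg.smote_k,
                                      seed=int(rng.integers(2**31 - 1)))
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
        )
        forest.fit(Xs, ys)
        imp = feature_importances(forest)
        full = np.zeros(self.X.shape[1])
        full[support] = imp
        return FullFitResult(self, forest, full)


@dataclass
class FullFitResult:
    """A single forest fitted on all subjects, with normalised importances."""

    model: RadiomicsForest
    forest: RandomForestClassifier
    importances: np.ndarray

    def top_percentile(self, percentile: float = 10.0) -> pd.Series:
        """The top-``percentile`` importance coefficients (48 of 480 at 10%)."""
        n = len(self.importances)
        k = int(round(n * percentile / 100.0))
        order = np.argsort(self.importances)[::-1][:k]
        return pd.Series(
            self.importances[order],
            index=[self.model.feature_names[i] for i in order],
        )


class CVResults:
    """Results of repeated nested cross-validation.

    Carries one :class:`FoldRecord` per (repeat, fold) cell with the
    held-out predictions, per-fold AUC and Brier score, and fold-level
    feature importances; exposes the aggregate statistics the analysis
    reports (mean +/- SD AUC and Brier over fold cells).
    """

    def __init__(self, model: RadiomicsForest, records: list[FoldRecord]):
        self.model = model
        self.records = records

    # ------------------------------------------------------------- aggregates
    @property
    def aucs(self) -> np.ndarray:
        """Per-fold AUCs, excluding single-class folds."""
        a = np.array([r.auc for r in self.records])
        return a[~np.isnan(a)]

    @property
    def briers(self) -> np.ndarray:
        return np.array([r.brier for r in self.records])

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std())

    @property
    def mean_brier(self) -> float:
        return float(self.briers.mean())

    @property
    def sd_brier(self) -> float:
        return float(self.briers.std())

    @property
    def n_excluded_folds(self) -> int:
        return int(np.isnan([r.auc for r in self.records]).sum())

    def mean_importances(self) -> pd.Series | None:
        """Importances averaged over fold fits (None under PCA)."""
        imps = [r.importances for r in self.records if r.importances is not None]
        if not imps:
            return None
        return pd.Series(np.mean(imps, axis=0), index=self.model.feature_names)

    def to_frame(self) -> pd.DataFrame:
        """Per-fold records as a tidy DataFrame."""
        return pd.DataFrame(
            {
                "repeat": [r.repeat for r in self.records],
                "fold": [r.fold for r in self.records],
                "auc": [r.auc for r in self.records],
                "brier": [r.brier for r in self.records],
                "n_features": [r.n_features_used for r in self.records],
            }
        )

    def fold_predictions(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """(test indices, y_true, y_prob) per fold cell, for model comparison."""
        return [(r.test_indices, r.y_true, r.y_prob) for r in self.records]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Repeated nested cross-validation results",
            "=" * 44,
            f"endpoint:        {self.model.endpoint}",
            f"subjects:        {len(self.model.y)} "
            f"({int(self.model.y.sum())} positive)",
            f"features:        {self.model.X.shape[1]}",
            f"forest:          {cfg.n_trees} trees",
            f"scheme:          {cfg.outer_folds}-fold x {cfg.repeats} repeats",
            f"dim reduction:   {cfg.dim_reduction}",
            f"oversampling:    {cfg.oversample}",
            "-" * 44,
            f"mean AUC:        {self.mean_auc:.3f} +/- {self.sd_auc:.3f}",
            f"mean Brier:      {self.mean_brier:.3f} +/- {self.sd_brier:.3f}",
            f"fold cells:      {len(self.records)} "
            f"({self.n_excluded_folds} excluded from AUC)",
        ]
        imp = self.mean_importances()
        if imp is not None:
            top = imp.sort_values(ascending=False).head(5)
            lines.append("top mean importances:")
            for name, v in top.items():
                lines.append(f"  {name:<40s} {v:.4f}")
        return "\n".join(lines)


def run_repeated_cv(features, labels, config: PipelineConfig | None = None,
                    feature_names=None, endpoint: str = "outcome") -> CVResults:
    """Functional wrapper around :class:`RadiomicsForest`."""
    return RadiomicsForest(
        features, labels, config=config, feature_names=feature_names,
        endpoint=endpoint,
    ).fit()
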