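"""Plot helpers for cross-validation AUC distributions and agreement."""

from __future__ import annotations

import numpy as np


def plot_auc_boxplots(distributions: dict[str, list[float]], ax=None,
                      trim_percentile: float = 2.5):
    """Outlier-trimmed boxplots of per-fold AUC distributions.

    ``distributions`` maps configuration labels to per-fold AUC lists; each
    is trimmed at ``trim_percentile`` / ``100 - trim_percentile`` before
    plotting.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(4, len(distributions)), 4))
    labels, data = [], []
    for label, aucs in distributions.items():
        a = np.asarray(aucs, dtype=float)
        a = a[~np.isnan(a)]
        if a.size:
            lo, hi = np.percentile(a, [trim_percentile, 100 - trim_percentile])
            a = a[(a >= lo) & (a <= hi)]
        labels.append(label)
        data.append(a)
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_ylabel("cross-validation AUC")
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_icc_category_histogram(agreement, ax=None):
    """Stacked relative ICC-category distribution per comparison."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    order = ["poor", "moderate", "good", "excellent"]
    pivot = (
        agreement.groupby(["comparison", "category"]).size().unstack(fill_value=0)
    )
    for cat in order:
        if cat not in pivot:
            pivot[cat] = 0
    pivot = pivot[order]
    rel = pivot.div(pivot.sum(axis=1), axis=0)
    bottom = np.zeros(len(rel))
    for cat in order:
        ax.bar(rel.index, rel[cat], bottom=bottom, label=cat)
        bottom += rel[cat].to_numpy()
    ax.set_ylabel("fraction of features")
    ax.tick_params(axis="x", rotation=90)
    ax.legend(fontsize=8)
    return ax
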