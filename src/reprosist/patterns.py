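"""Transformations behind the expression heatmaps and cluster groupings."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans


def log1p2(m: pd.DataFrame | np.ndarray):
    """log2(1 + x), the heatmap expression transform."""
    return np.log2(1.0 + m)


def zscore(m: pd.DataFrame, axis: int = 0) -> pd.DataFrame:
    """Z-score along ``axis`` (0 = within each column, 1 = within each row).

    Raises on zero-variance vectors, naming the offending gene/sample.
    """
    mean = m.mean(axis=axis)
    sd = m.std(axis=axis, ddof=0)
    bad = sd[sd == 0]
    if len(bad):
        raise ValueError(f"zero standard deviation for {list(bad.index[:5])}")
    return m.sub(mean, axis=1 - axis).div(sd, axis=1 - axis)


def before_after_normalize(m: pd.DataFrame, stage: pd.Series,
                           pseudocount: float | None = None) -> pd.DataFrame:
    """Stage-wise relative expression for before/after-NT heatmaps.

    Per gene, before-NT samples are divided by the gene's before-NT mean
    and after-NT samples by its after-NT mean; log2 is taken with a
    pseudocount (default 2^-10 of the matrix maximum); finally each sample
    column is z-scored over the selected genes.
    """
    stages = set(stage.reindex(m.columns))
    if stages - {"before-NT", "after-NT"} or stage.reindex(m.columns).isna().any():
        raise ValueError("every sample must be labeled before-NT or after-NT")
    if pseudocount is None:
        pseudocount = float(m.to_numpy().max()) * 2.0 ** -10
    out = m.astype(float).copy()
    for s in stages:
        cols = [c for c in m.columns if stage[c] == s]
        group_mean = m[cols].mean(axis=1)
        out[cols] = m[cols].div(group_mean + pseudocount, axis=0)
    out = np.log2(out + pseudocount)
    return zscore(out, axis=0)


def order_by_fold_change(m: pd.DataFrame, numerator_cols: list[str],
                         denominator_cols: list[str]) -> list:
    """Gene ordering by mean fold change (ascending log-ratio)."""
    pc = float(m.to_numpy().max()) * 2.0 ** -10
    ratio = np.log2((m[numerator_cols].mean(axis=1) + pc)
                    / (m[denominator_cols].mean(axis=1) + pc))
    return list(ratio.sort_values().index)


def kmeans_groups(m: pd.DataFrame, k: int = 10, seed: int = 0) -> pd.Series:
    """K-means row grouping (k-means++ init, Lloyd iterations, <= 300)."""
    if k < 1 or k > len(m):
        raise ValueError(f"k must be in [1, {len(m)}]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    labels = km.fit_predict(m.to_numpy(dtype=float))
    return pd.Series(labels, index=m.index, name="cluster")


def hierarchical_order(m: pd.DataFrame, method: str = "complete",
                       metric: str = "euclidean") -> list:
    """Row ordering from unsupervised hierarchical clustering
    (Euclidean distance, complete linkage, dendrogram leaf order)."""
    if len(m) < 2:
        return list(m.index)
    z = linkage(m.to_numpy(dtype=float), method=method, metric=metric)
    return [m.index[i] for i in leaves_list(z)]
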