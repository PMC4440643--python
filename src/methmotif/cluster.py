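"""K-means clustering of CpGs by their beta-value profiles.

Rows (CpGs) are clustered across samples with Lloyd's algorithm, k-means++
seeding and best-of-restarts selection by total within-cluster sum of
squares (WCSS). The WCSS curve over k = 1..k_max supports elbow-style
choice of k (the analyses here default to k = 5). Cluster indices are
reported in descending order of centroid mean beta, so cluster 1 is the
most methylated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ClusterResult:
    assignments: pd.Series      # cpg_id -> cluster index in 1..k
    centroids: np.ndarray       # k x n_samples, row i = centroid of cluster i+1
    wcss_total: float
    k: int
    seed: int
    restarts: int


def _impute_row_means(beta: pd.DataFrame) -> np.ndarray:
    X = beta.to_numpy(dtype=float)
    if np.isnan(X).any():
        row_means = np.nanmean(X, axis=1)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = row_means[idx[0]]
    return X


def _fit(X: np.ndarray, k: int, restarts: int, seed: int, init=None) -> KMeans:
    if init is not None:
        km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    return km.fit(X)


def kmeans_beta(beta: pd.DataFrame, k: int, restarts: int = 10, seed: int = 0) -> ClusterResult:
    """Best-of-restarts k-means over CpG rows (missing beta imputed by row mean)."""
    if beta.empty:
        raise ValueError("empty beta matrix")
    if not 1 <= k <= len(beta):
        raise ValueError(f"k={k} outside 1..{len(beta)}")
    X = _impute_row_means(beta)
    km = _fit(X, k, restarts, seed)
    return _as_result(beta, X, km, k, seed, restarts)


def _as_result(beta, X, km, k, seed, restarts) -> ClusterResult:
    # relabel clusters by descending centroid mean beta (cluster 1 = most methylated)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="mergesort")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = pd.Series(relabel[km.labels_], index=beta.index, name="cluster")
    centroids = km.cluster_centers_[order]
    return ClusterResult(assignments, centroids, float(km.inertia_), k, seed, restarts)


def wcss_curve(beta: pd.DataFrame, k_max: int = 10, restarts: int = 10, seed: int = 0):
    """(k, WCSS) for k = 1..k_max; guaranteed non-increasing in k.

    Besides the k-means++ restarts, each k >= 2 also tries an init derived
    from the k-1 solution (its centroids plus the worst-fit point), which
    makes the curve monotone by construction.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, len(beta))
    X = _impute_row_means(beta)
    curve = []
    prev = None
    for k in range(1, k_max + 1):
        km = _fit(X, k, restarts, seed)
        if prev is not None:
            dists = ((X - prev.cluster_centers_[prev.labels_]) ** 2).sum(axis=1)
            init = np.vstack([prev.cluster_centers_, X[np.argmax(dists)]])
            km_split = _fit(X, k, restarts, seed, init=init)
            if km_split.inertia_ < km.inertia_:
                km = km_split
        curve.append((k, float(km.inertia_)))
        prev = km
    return curve


def cluster_assignments_table(result: ClusterResult) -> pd.DataFrame:
    return result.assignments.rename_axis("cpg_id").reset_index()
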