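"""Cluster assignment and embedding-quality metrics.

Clusters on the 2-D embedding are found with seeded k-means (10 restarts);
when the cluster count is left open it is chosen over k = 2..min(6, n-2) to
maximize the mean silhouette.  Quality metrics are the mean pairwise
intra-cluster distance per cluster, the pooled mean cross-cluster pairwise
distance, the silhouette coefficient, and the Sammon mapping stress

    E = (1 / sum d*_ij) * sum (d*_ij - d_ij)^2 / d*_ij          (i < j)

between high-dimensional distances d* and embedding distances d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "QualityReport",
    "assign_clusters",
    "intra_inter_distances",
    "silhouette_values",
    "silhouette_score",
    "sammon_error",
    "quality_report",
]


@dataclass
class ClusterAssignment:
    """Labels per site plus the selection trace when k was chosen by silhouette."""

    labels: np.ndarray
    k: int
    method: str
    selection_trace: dict[int, float] = field(default_factory=dict)


def assign_clusters(Y: np.ndarray, k: int | None = None, seed: int = 0,
                    n_restarts: int = 10) -> ClusterAssignment:
    """Seeded k-means partitioning of an embedding.

    With ``k=None`` the count is chosen in {2, ..., min(6, n-2)} to maximize
    the mean silhouette.  Deterministic given the seed.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points to cluster")
    trace: dict[int, float] = {}
    if k is None:
        best_k, best_s = None, -np.inf
        for cand in range(2, min(6, n - 2) + 1):
            labels = KMeans(n_clusters=cand, n_init=n_restarts, random_state=seed).fit_predict(Y)
            s = silhouette_score(Y, labels)
            trace[cand] = s
            if s > best_s:
                best_k, best_s = cand, s
        k = best_k
        method = "kmeans(auto-k by silhouette)"
    else:
        if not 2 <= k <= n - 1:
            raise ValueError("k must lie in [2, n-1]")
        method = "kmeans(fixed k)"
    labels = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit_predict(Y)
    return ClusterAssignment(labels=labels, k=k, method=method, selection_trace=trace)


@dataclass
class QualityReport:
    """Embedding-quality metrics for one clustering."""

    intra_per_cluster: dict[int, float]
    singleton_clusters: list[int]
    inter_mean: float
    silhouette_mean: float
    silhouette_per_point: np.ndarray
    sammon: float | None = None

    def to_dict(self) -> dict:
        return {
            "intra_per_cluster": {str(c): v for c, v in self.intra_per_cluster.items()},
            "singleton_clusters": list(self.singleton_clusters),
            "inter_mean": self.inter_mean,
            "silhouette_mean": self.silhouette_mean,
            "silhouette_per_point": [float(s) for s in self.silhouette_per_point],
            "sammon": self.sammon,
        }


def intra_inter_distances(Y: np.ndarray, labels: np.ndarray) -> tuple[dict[int, float], list[int], float]:
    """Mean pairwise distance within each cluster and across clusters.

    Returns (intra per cluster, singleton cluster ids, pooled inter mean).
    A singleton cluster has no within pair; its intra distance is reported
    as 0 and its id flagged.
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    D = squareform(pdist(Y))
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    intra: dict[int, float] = {}
    singletons: list[int] = []
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            intra[int(c)] = 0.0
            singletons.append(int(c))
        else:
            sub = D[np.ix_(idx, idx)]
            intra[int(c)] = float(sub[np.triu_indices(idx.size, k=1)].mean())
    cross = labels[:, None] != labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    cross_iu = cross[iu]
    inter = float(D[iu][cross_iu].mean()) if cross_iu.any() else 0.0
    return intra, singletons, inter


def silhouette_values(Y_or_D: np.ndarray, labels: np.ndarray, precomputed: bool = False) -> np.ndarray:
    """Per-point silhouette s(i) = (b_i - a_i)/max(a_i, b_i).

    a_i is the mean distance of i to its own cluster (excluding i); b_i the
    smallest mean distance to another cluster.  Points in singleton
    clusters get s = 0 by convention.
    """
    labels = np.asarray(labels)
    D = np.asarray(Y_or_D, dtype=float) if precomputed else squareform(pdist(np.asarray(Y_or_D, dtype=float)))
    n = len(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        ci = labels[i]
        if sizes[ci] == 1:
            continue
        a = D[i, labels == ci].sum() / (sizes[ci] - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != ci)
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return s


def silhouette_score(Y_or_D: np.ndarray, labels: np.ndarray, precomputed: bool = False) -> float:
    """Mean silhouette over all points."""
    return float(silhouette_values(Y_or_D, labels, precomputed=precomputed).mean())


def sammon_error(X: np.ndarray, Y: np.ndarray) -> float:
    """Sammon mapping stress between high-dimensional X and embedding Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    d_star = pdist(X)
    if np.any(d_star == 0):
        D = squareform(d_star)
        np.fill_diagonal(D, np.inf)
        i, j = np.argwhere(D == 0)[0]
        raise ValueError(f"rows {i} and {j} of X coincide; Sammon stress undefined")
    d = pdist(Y)
    return float(np.sum((d_star - d) ** 2 / d_star) / d_star.sum())


def quality_report(Y: np.ndarray, labels: np.ndarray, X: np.ndarray | None = None) -> QualityReport:
    """Assemble every quality metric for one embedding + clustering."""
    intra, singletons, inter = intra_inter_distances(Y, labels)
    s = silhouette_values(Y, labels)
    sammon = sammon_error(X, Y) if X is not None else None
    return QualityReport(
        intra_per_cluster=intra,
        singleton_clusters=singletons,
        inter_mean=inter,
        silhouette_mean=float(s.mean()),
        silhouette_per_point=s,
        sammon=sammon,
    )
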