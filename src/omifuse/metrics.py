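"""Internal cluster-validity indices: Davies-Bouldin, Calinski-Harabasz, silhouette.

DBI and CHI are implemented directly from their definitions so that the
degenerate cases carry the contracts this pipeline needs (coincident
centroids are an error naming the offending pair; zero within-cluster
scatter yields an infinite CHI rather than an exception); both agree with
the scikit-learn implementations on generic data, which the test suite
uses as an independent cross-check.  Silhouette delegates to scikit-learn
and accepts a precomputed distance matrix, which is how the pipeline scores
candidate cluster counts on the fused 1 - a distance.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import silhouette_score

__all__ = ["davies_bouldin", "calinski_harabasz", "silhouette"]


def _check_labels(labels: np.ndarray, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("labels length does not match the number of points")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two clusters")
    return labels


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index on Euclidean feature space (lower is better).

    DBI = (1/n) * sum_i max_{j != i} (a_i + a_j) / d_ij, where a_i is the
    mean distance of cluster i's points to their centroid and d_ij the
    distance between centroids.  Coincident centroids make the ratio
    undefined and raise, naming the cluster pair.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = _check_labels(labels, X.shape[0])
    uniq = np.unique(labels)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array([
        np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean()
        for i, c in enumerate(uniq)
    ])
    ncl = len(uniq)
    worst = np.zeros(ncl)
    for i in range(ncl):
        for j in range(ncl):
            if i == j:
                continue
            d_ij = np.linalg.norm(centroids[i] - centroids[j])
            if d_ij == 0:
                raise ValueError(
                    f"clusters {uniq[i]!r} and {uniq[j]!r} have coincident centroids"
                )
            worst[i] = max(worst[i], (scatter[i] + scatter[j]) / d_ij)
    return float(worst.mean())


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz variance-ratio criterion (higher is better).

    CHI = [Tr(B_k)/(k-1)] / [Tr(W_k)/(N-k)] with between- and within-cluster
    scatter traces about the centroids and grand mean.  Perfectly tight
    clusters (Tr(W_k) = 0) give +inf, not an exception.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    labels = _check_labels(labels, N)
    uniq = np.unique(labels)
    k = len(uniq)
    if N <= k:
        raise ValueError("need more points than clusters")
    grand = X.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for c in uniq:
        pts = X[labels == c]
        centroid = pts.mean(axis=0)
        tr_b += len(pts) * float(np.sum((centroid - grand) ** 2))
        tr_w += float(np.sum((pts - centroid) ** 2))
    if tr_w == 0.0:
        return float("inf")
    return (tr_b / (k - 1)) / (tr_w / (N - k))


def silhouette(X: np.ndarray, labels: np.ndarray, metric: str = "euclidean") -> float:
    """Mean silhouette score; pass ``metric="precomputed"`` for distances."""
    X = np.asarray(X, dtype=float)
    labels = _check_labels(np.asarray(labels), X.shape[0])
    return float(silhouette_score(X, labels, metric=metric))
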