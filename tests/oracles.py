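"""Brute-force reference implementations used as independent oracles.

Everything here is written as plain double loops straight from the
definitions, deliberately sharing no code with the package.
"""

import math

import numpy as np


def euclidean_brute(X):
    n = len(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = math.sqrt(sum((X[i][t] - X[j][t]) ** 2 for t in range(len(X[i]))))
    return d


def knn_brute(X, k):
    """Neighbor lists under Euclidean distance, ties broken by index."""
    d = euclidean_brute(X)
    n = len(X)
    out = []
    for i in range(n):
        order = sorted((d[i, j], j) for j in range(n) if j != i)
        out.append([j for _, j in order[:k]])
    return out


def scaled_exponential_brute(d, K, mu):
    """One-line-per-term transcription of the scaled-exponential kernel."""
    n = d.shape[0]
    knn_mean = np.zeros(n)
    for i in range(n):
        others = sorted(d[i, j] for j in range(n) if j != i)
        knn_mean[i] = sum(others[:K]) / K
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            eps = (knn_mean[i] + knn_mean[j] + d[i, j]) / 3.0
            a[i, j] = math.exp(-(d[i, j] ** 2) / (mu * eps)) if i != j else 1.0
    return a


def mean_prediction_brute(values, neighbor_lists):
    n = len(values)
    pred = np.zeros_like(np.asarray(values, dtype=float))
    for i in range(n):
        nbrs = neighbor_lists[i]
        for j in nbrs:
            pred[i] += values[j]
        pred[i] /= len(nbrs)
    return pred


def sigma_brute(X, neighbor_lists):
    d = euclidean_brute(X)
    return np.array([
        sum(d[i, j] for j in nbrs) / len(nbrs)
        for i, nbrs in enumerate(neighbor_lists)
    ])


def theta_brute(observed, predicted, sigma):
    n = len(observed)
    out = np.zeros(n)
    for i in range(n):
        resid = math.sqrt(sum((observed[i][t] - predicted[i][t]) ** 2
                              for t in range(len(observed[i]))))
        out[i] = math.exp(-resid / sigma[i])
    return out


def davies_bouldin_brute(X, labels):
    X = np.asarray(X, dtype=float)
    clusters = sorted(set(labels))
    cent = {c: X[np.asarray(labels) == c].mean(axis=0) for c in clusters}
    a = {c: np.mean([np.linalg.norm(x - cent[c]) for x in X[np.asarray(labels) == c]])
         for c in clusters}
    total = 0.0
    for ci in clusters:
        best = 0.0
        for cj in clusters:
            if ci == cj:
                continue
            r = (a[ci] + a[cj]) / np.linalg.norm(cent[ci] - cent[cj])
            best = max(best, r)
        total += best
    return total / len(clusters)


def calinski_harabasz_brute(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    grand = X.mean(axis=0)
    trb = sum((labels == c).sum() * np.sum((X[labels == c].mean(axis=0) - grand) ** 2)
              for c in clusters)
    trw = sum(np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2)
              for c in clusters)
    k, N = len(clusters), len(X)
    return (trb / (k - 1)) / (trw / (N - k))


def silhouette_brute(d, labels):
    """Mean silhouette from a square distance matrix; singletons get 0."""
    labels = np.asarray(labels)
    n = len(labels)
    svals = []
    for i in range(n):
        own = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:
            svals.append(0.0)
            continue
        a = sum(d[i, j] for j in own) / len(own)
        b = math.inf
        for c in set(labels.tolist()):
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(d[i, j] for j in members) / len(members))
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def logrank_brute(times, events, groups):
    """Observed-minus-expected log-rank chi-square over pooled event times.

    Two-group and k-group version using the standard hypergeometric
    variance/covariance at each distinct event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq_groups = sorted(set(groups.tolist()))
    g = len(uniq_groups)
    event_times = sorted(set(times[events == 1].tolist()))
    O_minus_E = np.zeros(g - 1)
    V = np.zeros((g - 1, g - 1))
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = ((times == t) & (events == 1)).sum()
        n_g = np.array([(at_risk & (groups == c)).sum() for c in uniq_groups])
        d_g = np.array([((times == t) & (events == 1) & (groups == c)).sum()
                        for c in uniq_groups])
        e_g = d_t * n_g / n_t
        O_minus_E += (d_g - e_g)[:-1]
        if n_t > 1:
            for a in range(g - 1):
                for b in range(g - 1):
                    if a == b:
                        V[a, b] += (d_t * (n_g[a] / n_t) * (1 - n_g[a] / n_t)
                                    * (n_t - d_t) / (n_t - 1))
                    else:
                        V[a, b] -= (d_t * n_g[a] * n_g[b] / n_t**2
                                    * (n_t - d_t) / (n_t - 1))
    if np.allclose(O_minus_E, 0):
        return 0.0
    return float(O_minus_E @ np.linalg.solve(V, O_minus_E))
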