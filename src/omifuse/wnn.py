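"""Per-patient omics weights from within- vs cross-omics KNN prediction.

The explainability core of the pipeline.  For every omics layer t and
patient i we ask: how well is patient i's profile in layer t reconstructed
by averaging its k nearest neighbors, when the neighborhood is found

* in layer t itself (within-omics prediction), versus
* in each other layer u (cross-omics prediction)?

Reconstruction quality is an exponential kernel of the Euclidean residual,

    theta_{t,u,i} = exp(-||x_{t,i} - xhat_{t,u,i}|| / sigma_{t,i}),

with a per-patient bandwidth sigma_{t,i} equal to the mean distance from i
to its k nearest neighbors in layer t.  A layer whose own neighborhood
structure predicts its profiles much better than the other layers'
neighborhoods do carries real, layer-specific signal for that patient; the
ratio

    s_{t,i} = theta_{t,t,i} / (mean_{u != t} theta_{t,u,i} + epsilon)

captures this, and a softmax over layers turns the ratios into per-patient
weights that sum to one.  With more than two layers the cross term is the
arithmetic mean over the other layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import CohortBundle, OmicsLayer

logger = logging.getLogger(__name__)

__all__ = [
    "KNNGraph",
    "PredictionSimilarity",
    "WeightMatrix",
    "build_knn",
    "within_prediction",
    "cross_prediction",
    "bandwidth",
    "prediction_similarity",
    "compute_prediction_similarities",
    "omics_weights",
    "cohort_weights",
]

SIGMA_FLOOR = 1e-12
_S_CLIP = 50.0  # exp(50) is finite; clipping cannot change the softmax argmax


@dataclass
class KNNGraph:
    """Per-patient ordered k-nearest-neighbor lists for one omics layer."""

    patients: list[str]
    k: int
    neighbors: np.ndarray  # (n, k) int, no self-loops
    distances: np.ndarray  # (n, k), nondecreasing along each row

    def __post_init__(self) -> None:
        n = len(self.patients)
        if self.neighbors.shape != (n, self.k) or self.distances.shape != (n, self.k):
            raise ValueError("neighbor/distance arrays do not match (n, k)")
        if np.any(self.neighbors == np.arange(n)[:, None]):
            raise ValueError("KNN graph contains self-loops")
        if np.any(np.diff(self.distances, axis=1) < 0):
            raise ValueError("neighbor distances must be nondecreasing")


@dataclass
class PredictionSimilarity:
    """theta and sigma values for every omics layer over one cohort.

    ``theta_cross[t, u]`` holds theta_{t,u,i}: layer t's profiles predicted
    from neighborhoods of layer u.  The diagonal ``theta_cross[t, t]``
    duplicates ``theta_within[t]`` for convenience.
    """

    patients: list[str]
    omics: list[str]
    theta_within: np.ndarray  # (T, n)
    theta_cross: np.ndarray   # (T, T, n)
    sigma: np.ndarray         # (T, n)


@dataclass
class WeightMatrix:
    """Patients x omics explainability weights; rows sum to one."""

    patients: list[str]
    omics: list[str]
    w: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        if self.w.shape != (len(self.patients), len(self.omics)):
            raise ValueError("weight matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.patients, columns=self.omics)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="patient")


def build_knn(layer: OmicsLayer, k: int = 20) -> KNNGraph:
    """K nearest other patients under Euclidean distance, ties by index."""
    n = layer.n_patients
    if n < 2:
        raise ValueError("need at least two patients to build a KNN graph")
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > n - 1:
        logger.warning("k=%d exceeds n-1=%d; clamping", k, n - 1)
        k = n - 1
    d = squareform(pdist(layer.values, metric="euclidean"))
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    dists = np.take_along_axis(d, order, axis=1)
    return KNNGraph(patients=list(layer.patients), k=k, neighbors=order, distances=dists)


def within_prediction(layer: OmicsLayer, graph: KNNGraph) -> np.ndarray:
    """Predict each profile as the mean of its same-layer neighbors."""
    if graph.patients != layer.patients:
        raise ValueError("graph and layer patient orderings differ")
    return layer.values[graph.neighbors].mean(axis=1)


def cross_prediction(target_layer: OmicsLayer, other_graph: KNNGraph) -> np.ndarray:
    """Predict each profile of ``target_layer`` from another layer's neighborhoods."""
    if other_graph.patients != target_layer.patients:
        raise ValueError("graph and layer patient orderings differ")
    return target_layer.values[other_graph.neighbors].mean(axis=1)


def bandwidth(graph: KNNGraph, floor: float = SIGMA_FLOOR) -> np.ndarray:
    """Per-patient kernel bandwidth: mean distance to the k nearest neighbors.

    Floored at a small positive constant so the similarity kernel stays
    defined on degenerate duplicate-profile data.
    """
    return np.maximum(graph.distances.mean(axis=1), floor)


def prediction_similarity(
    observed: np.ndarray,
    predicted: np.ndarray,
    sigma: np.ndarray | float,
    squared: bool = False,
) -> np.ndarray:
    """Exponential kernel of the observed-vs-predicted Euclidean residual.

    By default the exponent uses the unsquared L2 norm,
    ``exp(-||obs - pred|| / sigma)``; ``squared=True`` switches to the
    Gaussian variant ``exp(-||obs - pred||^2 / sigma)``.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    resid = np.linalg.norm(observed - predicted, axis=1)
    if squared:
        resid = resid**2
    return np.exp(-resid / sigma)


def compute_prediction_similarities(
    layers: list[OmicsLayer],
    k: int = 20,
    squared: bool = False,
    graphs: list[KNNGraph] | None = None,
) -> PredictionSimilarity:
    """Within- and cross-omics theta values plus bandwidths for a cohort.

    Within-omics neighborhoods exclude the patient itself (a distance-zero
    self neighbor would make within-prediction trivially perfect).
    """
    if not layers:
        raise ValueError("need at least one layer")
    ref = layers[0].patients
    for layer in layers:
        if layer.patients != ref:
            raise ValueError(f"layer {layer.name!r} does not share the patient ordering")
    if graphs is None:
        graphs = [build_knn(layer, k=k) for layer in layers]
    T, n = len(layers), len(ref)
    sigma = np.vstack([bandwidth(g) for g in graphs])
    theta_cross = np.empty((T, T, n))
    for t, layer in enumerate(layers):
        for u, graph in enumerate(graphs):
            pred = cross_prediction(layer, graph)
            theta_cross[t, u] = prediction_similarity(
                layer.values, pred, sigma[t], squared=squared
            )
    theta_within = np.stack([theta_cross[t, t] for t in range(T)])
    return PredictionSimilarity(
        patients=list(ref),
        omics=[layer.name for layer in layers],
        theta_within=theta_within,
        theta_cross=theta_cross,
        sigma=sigma,
    )


def omics_weights(
    similarities: PredictionSimilarity,
    epsilon: float = 1e-8,
) -> WeightMatrix:
    """Softmax the within/cross similarity ratios into per-patient weights.

    For a single layer the weights are trivially all one.  The ratio is
    clipped at 50 before exponentiation to avoid overflow when the cross
    similarity is vanishingly small; this cannot change which layer wins and
    perturbs weights only when one weight already saturates.
    """
    T = len(similarities.omics)
    n = len(similarities.patients)
    if not np.isfinite(similarities.theta_cross).all():
        t, u, i = np.argwhere(~np.isfinite(similarities.theta_cross))[0]
        raise ValueError(
            f"non-finite prediction similarity for patient "
            f"{similarities.patients[i]!r}, omics {similarities.omics[t]!r} "
            f"(predicted from {similarities.omics[u]!r})"
        )
    if T == 1:
        return WeightMatrix(
            patients=list(similarities.patients),
            omics=list(similarities.omics),
            w=np.ones((n, 1)),
            epsilon=epsilon,
        )
    s = np.empty((T, n))
    for t in range(T):
        others = [u for u in range(T) if u != t]
        cross = similarities.theta_cross[t, others].mean(axis=0)
        s[t] = similarities.theta_within[t] / (cross + epsilon)
    s = np.minimum(s, _S_CLIP)
    e = np.exp(s - s.max(axis=0, keepdims=True))
    w = (e / e.sum(axis=0, keepdims=True)).T
    return WeightMatrix(
        patients=list(similarities.patients),
        omics=list(similarities.omics),
        w=w,
        epsilon=epsilon,
    )


def cohort_weights(
    bundle: CohortBundle,
    k: int = 20,
    epsilon: float = 1e-8,
    squared: bool = False,
) -> WeightMatrix:
    """Convenience wrapper: prediction similarities + softmax on a bundle."""
    sims = compute_prediction_similarities(bundle.layers, k=k, squared=squared)
    return omics_weights(sims, epsilon=epsilon)
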