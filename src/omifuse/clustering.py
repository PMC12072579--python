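"""Consensus clustering of the integrated similarity and choice of k.

Subtypes are extracted by subsampled consensus clustering: in each of
``reps`` iterations a random 80% of the cohort is drawn without
replacement, average-linkage hierarchical clustering is run on the induced
1 - a distance and cut at k, and the consensus matrix records, for every
patient pair, the fraction of co-sampled iterations in which the pair was
co-clustered.  Final labels come from an average-linkage cut of the
consensus-derived distance 1 - consensus.  The number of clusters is chosen
by scanning k = 2..10 and keeping the k whose labels maximize the mean
silhouette on the integrated distance (ties go to the smaller k); callers
may override k with prior knowledge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .affinity import DistanceMatrix
from .fusion import IntegratedAffinity
from .wnn import WeightMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusRun",
    "SubtypeResult",
    "affinity_to_distance",
    "consensus_cluster",
    "select_k",
]


@dataclass
class ConsensusRun:
    """One consensus-clustering run at a fixed cluster count k."""

    k: int
    patients: list[str]
    consensus: np.ndarray
    labels: np.ndarray
    reps: int
    subsample_fraction: float
    seed: int


@dataclass
class SubtypeResult:
    """Final subtype assignment with the evidence used to choose k."""

    patients: list[str]
    labels: np.ndarray
    k: int
    silhouette_by_k: pd.DataFrame
    consensus_run: ConsensusRun
    per_subtype_weight_medians: pd.DataFrame | None = None

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient": self.patients, "subtype": self.labels})


def affinity_to_distance(integrated: IntegratedAffinity) -> DistanceMatrix:
    """Turn a [0, 1] similarity into the distance d = 1 - a (zero diagonal)."""
    d = 1.0 - integrated.a
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    np.clip(d, 0.0, None, out=d)
    return DistanceMatrix(patients=list(integrated.patients), d=d)


def _best_k(table: pd.DataFrame) -> int:
    """Argmax-silhouette k; silhouettes tied within 1e-12 go to the smaller k."""
    if table["silhouette"].isna().all():
        raise ValueError("no candidate k produced a valid clustering")
    best_val = np.nanmax(table["silhouette"].to_numpy())
    return int(table.loc[table["silhouette"] >= best_val - 1e-12, "k"].min())


def _hier_cut(d: np.ndarray, k: int, method: str = "average") -> np.ndarray:
    """Average-linkage cut of a square distance matrix into k groups."""
    Z = linkage(squareform(d, checks=False), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    integrated: IntegratedAffinity,
    k: int,
    reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    linkage_method: str = "average",
) -> ConsensusRun:
    """Subsampled hierarchical consensus clustering at a fixed k.

    consensus(i, j) is the number of iterations in which i and j landed in
    the same cluster divided by the number in which both were sampled; the
    diagonal is 1 by convention.  A pair never co-sampled gets consensus 0
    with a warning (raise ``reps`` if this happens).  Fully deterministic
    given ``seed``.
    """
    n = len(integrated.patients)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must lie in [2, n-1] (got k={k}, n={n})")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    d = affinity_to_distance(integrated).d
    m = int(np.ceil(subsample_fraction * n))
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        labels = _hier_cut(d[np.ix_(idx, idx)], k, method=linkage_method)
        co = (labels[:, None] == labels[None, :]).astype(float)
        block = np.ix_(idx, idx)
        together[block] += co
        sampled[block] += 1.0
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        logger.warning(
            "%d patient pair(s) never co-sampled in %d reps; their consensus is 0",
            int(never.sum()) // 2, reps,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    final = _hier_cut(1.0 - consensus, k, method=linkage_method)
    if len(np.unique(final)) < k:
        logger.warning("consensus cut produced %d < k=%d clusters",
                       len(np.unique(final)), k)
    return ConsensusRun(
        k=k,
        patients=list(integrated.patients),
        consensus=consensus,
        labels=final,
        reps=reps,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def select_k(
    integrated: IntegratedAffinity,
    k_min: int = 2,
    k_max: int = 10,
    reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    weights: WeightMatrix | None = None,
    features: np.ndarray | None = None,
) -> SubtypeResult:
    """Scan candidate cluster counts and keep the best-silhouette k.

    Each candidate k gets its own consensus run; among silhouettes within
    1e-12 of the maximum the smallest k wins.  When ``features`` (a
    patients x features matrix, typically the concatenated standardized
    layers) is supplied, silhouettes are computed in that Euclidean space -
    the recommended substrate, since the scaled-exponential kernel
    compresses fused similarities into a narrow band in high dimension and
    leaves silhouettes on the 1 - a distance nearly flat.  Without
    ``features`` the 1 - a integrated distance is used.  When a
    :class:`WeightMatrix` is supplied the result also carries per-subtype
    median omics weights (the subtype-level explainability readout).
    """
    n = len(integrated.patients)
    if k_max > n - 1:
        logger.warning("k_max=%d exceeds n-1=%d; clamping", k_max, n - 1)
        k_max = n - 1
    if k_min < 2 or k_min > k_max:
        raise ValueError(f"invalid k range [{k_min}, {k_max}]")
    if features is not None:
        features = np.asarray(features, dtype=float)
        if features.shape[0] != n:
            raise ValueError("feature matrix rows do not match the cohort size")
    d = affinity_to_distance(integrated).d
    ks = list(range(k_min, k_max + 1))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(ks)) % (2**31)
    runs: dict[int, ConsensusRun] = {}
    sils: list[float] = []
    for k, child in zip(ks, child_seeds):
        run = consensus_cluster(
            integrated, k, reps=reps, subsample_fraction=subsample_fraction,
            seed=int(child),
        )
        runs[k] = run
        if len(np.unique(run.labels)) < 2:
            sils.append(np.nan)
        elif features is not None:
            sils.append(float(silhouette_score(features, run.labels)))
        else:
            sils.append(float(silhouette_score(d, run.labels, metric="precomputed")))
    table = pd.DataFrame({"k": ks, "silhouette": sils})
    best_k = _best_k(table)
    best = runs[best_k]
    medians = None
    if weights is not None:
        wdf = weights.to_frame()
        wdf["subtype"] = best.labels
        medians = wdf.groupby("subtype").median()
    return SubtypeResult(
        patients=list(integrated.patients),
        labels=best.labels,
        k=best_k,
        silhouette_by_k=table,
        consensus_run=best,
        per_subtype_weight_medians=medians,
    )
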