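"""Per-omics patient similarity via the scaled-exponential distance kernel.

The kernel is the one popularized by similarity-network-fusion approaches:
pairwise Euclidean distances are turned into affinities with a locally
adaptive bandwidth built from each patient's K-nearest-neighbor distances,

    a(i, j) = exp(-d(i, j)^2 / (mu * eps(i, j))),
    eps(i, j) = (mean_{l in N_i} d(i, l) + mean_{l in N_j} d(j, l) + d(i, j)) / 3,

where ``N_i`` is the set of the K nearest *other* patients of i.  The
defaults K = 20 and mu = 0.5 are the conventional ones.  Only the kernel is
provided here; the iterative cross-diffusion step of full SNF is
deliberately out of scope (the fusion rule of this package is the
per-patient weighted sum in :mod:`omifuse.fusion`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import OmicsLayer

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "AffinityMatrix",
    "pairwise_euclidean",
    "scaled_exponential_affinity",
]

_EPS_FLOOR = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative patient x patient distances with zero diagonal."""

    patients: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.patients)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match patient list")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class AffinityMatrix:
    """Symmetric patient x patient similarity in (0, 1], unit diagonal."""

    patients: list[str]
    a: np.ndarray
    omics: str

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.patients)
        if self.a.shape != (n, n):
            raise ValueError("affinity matrix shape does not match patient list")
        if not np.allclose(self.a, self.a.T, atol=1e-12):
            raise ValueError("affinity matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.patients, columns=self.patients)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def pairwise_euclidean(layer: OmicsLayer) -> DistanceMatrix:
    """Exact Euclidean distances between patient feature profiles."""
    if layer.n_patients < 2:
        raise ValueError("need at least two patients for pairwise distances")
    if not layer.complete:
        raise ValueError(f"layer {layer.name!r} has missing entries")
    d = squareform(pdist(layer.values, metric="euclidean"))
    return DistanceMatrix(patients=list(layer.patients), d=d)


def scaled_exponential_affinity(
    dist: DistanceMatrix,
    K: int = 20,
    mu: float = 0.5,
    omics: str = "",
) -> AffinityMatrix:
    """Apply the scaled-exponential kernel to a distance matrix.

    Parameters
    ----------
    dist
        Pairwise patient distances.
    K
        Neighborhood size for the adaptive bandwidth; must be < n_patients.
    mu
        Kernel scale (often called sigma in SNF implementations); > 0.

    The self-affinity a(i, i) is exp(0) = 1.  On duplicate-heavy data the
    bandwidth eps(i, j) can vanish for an off-diagonal pair; it is then
    floored at machine-epsilon scale with a warning so the kernel stays
    defined (the pair gets affinity ~= 1, as duplicates should).
    """
    n = len(dist.patients)
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < n_patients (got K={K}, n={n})")
    if mu <= 0:
        raise ValueError("mu must be positive")
    d = dist.d
    # mean distance to each patient's K nearest other patients
    masked = d.copy()
    np.fill_diagonal(masked, np.inf)
    knn_means = np.sort(masked, axis=1)[:, :K].mean(axis=1)
    eps = (knn_means[:, None] + knn_means[None, :] + d) / 3.0
    off = ~np.eye(n, dtype=bool)
    if np.any(eps[off] <= 0):
        logger.warning("flooring %d zero bandwidth value(s) (duplicate-heavy data)",
                       int((eps[off] <= 0).sum()))
        eps = np.maximum(eps, _EPS_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.exp(-(d**2) / (mu * eps))
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0  # exact symmetry despite floating-point noise
    return AffinityMatrix(patients=list(dist.patients), a=a, omics=omics or "unnamed")


def read_affinity_tsv(path: str | Path, omics: str = "") -> AffinityMatrix:
    """Round-trip reader for :meth:`AffinityMatrix.write_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column patient ids differ")
    return AffinityMatrix(patients=list(df.index), a=df.to_numpy(dtype=float),
                          omics=omics or "unnamed")
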