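"""Weighted integration of per-omics affinity matrices.

The integrated similarity between patients i and j is the per-patient
convex combination of the omics affinities,

    a(i, j) = sum_t w_{t,i} * a_t(i, j),

using row i's weights.  Because the weights belong to i, the raw sum is not
symmetric; it is symmetrized as (A + A^T) / 2, which equals averaging the
(i, j)- and (j, i)-weighted values.  The result is then min-max normalized
over its off-diagonal entries (the diagonal is pinned to 1, the
self-similarity) so the fused similarities span [0, 1] regardless of how
concentrated the kernel affinities were.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import AffinityMatrix
from .wnn import WeightMatrix

__all__ = ["IntegratedAffinity", "integrate", "minmax_normalize"]


@dataclass
class IntegratedAffinity:
    """Fused patient similarity matrix, min-max normalized into [0, 1]."""

    patients: list[str]
    a: np.ndarray
    symmetrized: bool = True

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.patients)
        if self.a.shape != (n, n):
            raise ValueError("integrated matrix shape does not match patient list")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.patients, columns=self.patients)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def minmax_normalize(a: np.ndarray, include_diagonal: bool = False) -> np.ndarray:
    """Min-max rescale a similarity matrix; diagonal pinned to 1 by default.

    With ``include_diagonal=False`` (default) the minimum and maximum are
    taken over off-diagonal entries only, so the unit self-similarity cannot
    distort the range, and the diagonal of the result is set to 1.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    sel = np.ones_like(a, dtype=bool) if include_diagonal else ~np.eye(n, dtype=bool)
    mn, mx = a[sel].min(), a[sel].max()
    if mx == mn:
        raise ValueError("constant affinity matrix: min-max normalization undefined")
    out = (a - mn) / (mx - mn)
    if not include_diagonal:
        np.fill_diagonal(out, 1.0)
    return out


def integrate(
    affinities: list[AffinityMatrix],
    weights: WeightMatrix,
    symmetrize: bool = True,
    include_diagonal: bool = False,
) -> IntegratedAffinity:
    """Fuse per-omics affinities with per-patient weights and normalize.

    ``affinities`` must be listed in the same omics order as the weight
    columns and share one patient ordering.  Options expose the two
    ambiguous conventions: skipping symmetrization, and including the
    diagonal in the min-max range.
    """
    if not affinities:
        raise ValueError("need at least one affinity matrix")
    ref = affinities[0].patients
    for aff in affinities:
        if aff.patients != ref:
            raise ValueError(f"affinity {aff.omics!r} does not share the patient ordering")
    if weights.patients != ref:
        raise ValueError("weight matrix patient ordering differs from affinities")
    if len(affinities) != len(weights.omics):
        raise ValueError(
            f"{len(affinities)} affinity matrices but {len(weights.omics)} weight columns"
        )
    stack = np.stack([aff.a for aff in affinities])         # (T, n, n)
    raw = np.einsum("it,tij->ij", weights.w, stack)
    if symmetrize:
        raw = (raw + raw.T) / 2.0
    normed = minmax_normalize(raw, include_diagonal=include_diagonal)
    return IntegratedAffinity(patients=list(ref), a=normed, symmetrized=symmetrize)
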