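"""Loading, filtering, intersection and standardization of omics matrices.

A cohort is represented as a set of :class:`OmicsLayer` objects (patients x
features, one per omics type) that, after intersection, share a single
patient ordering.  All downstream geometry (Euclidean distances, affinity
kernels, KNN prediction) assumes complete, feature-standardized layers, so
this module is the only place where missingness and scale are handled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsLayer",
    "CohortBundle",
    "load_layer",
    "filter_missing",
    "normalize_layer",
    "intersect_cohort",
    "shift_rescale",
]


@dataclass
class OmicsLayer:
    """One omics type's patients x features matrix with a missingness mask.

    Parameters
    ----------
    name
        Short label, e.g. ``"mRNA"`` or ``"methylation"``.
    patients, features
        Ordered, unique identifiers for rows and columns of ``values``.
    values
        Real matrix of shape ``(n_patients, n_features)``.  Missing entries
        are NaN and flagged ``False`` in ``mask``.
    mask
        Boolean availability matrix, same shape as ``values``; ``True``
        means the entry was observed.
    normalized
        Whether features have been centered/scaled by :func:`normalize_layer`.
    """

    name: str
    patients: list[str]
    features: list[str]
    values: np.ndarray
    mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(set(self.patients)) != len(self.patients):
            raise ValueError(f"layer {self.name!r}: duplicate patient identifiers")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"layer {self.name!r}: duplicate feature identifiers")
        expected = (len(self.patients), len(self.features))
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(
                f"layer {self.name!r}: shape mismatch, values {self.values.shape}, "
                f"mask {self.mask.shape}, expected {expected}"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())

    def to_frame(self) -> pd.DataFrame:
        """Patients x features DataFrame; missing entries become NaN."""
        vals = self.values.copy()
        vals[~self.mask] = np.nan
        return pd.DataFrame(vals, index=self.patients, columns=self.features)

    def subset_patients(self, patients: list[str]) -> "OmicsLayer":
        idx = [self.patients.index(p) for p in patients]
        return OmicsLayer(
            name=self.name,
            patients=list(patients),
            features=list(self.features),
            values=self.values[idx],
            mask=self.mask[idx],
            normalized=self.normalized,
        )


@dataclass
class CohortBundle:
    """Omics layers over one shared, identically ordered patient cohort."""

    layers: list[OmicsLayer]
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a cohort needs at least one omics layer")
        ref = self.layers[0].patients
        if len(ref) < 2:
            raise ValueError("a cohort needs at least two patients")
        for layer in self.layers[1:]:
            if layer.patients != ref:
                raise ValueError(
                    f"layer {layer.name!r} does not share the cohort patient ordering"
                )

    @property
    def patients(self) -> list[str]:
        return self.layers[0].patients

    @property
    def omics(self) -> list[str]:
        return [layer.name for layer in self.layers]


def load_layer(
    path: str | Path,
    name: str,
    orientation: str = "rows-are-patients",
) -> OmicsLayer:
    """Read a delimited patients x features table into an :class:`OmicsLayer`.

    The first column holds row identifiers; the delimiter (tab or comma) is
    sniffed from the file.  Empty cells and the usual NA spellings are
    treated as missing.  With ``orientation="rows-are-features"`` the table
    is transposed after reading.
    """
    if orientation not in ("rows-are-patients", "rows-are-features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "rows-are-features":
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    dup_rows = df.index[df.index.duplicated()]
    if len(dup_rows):
        raise ValueError(f"{path}: duplicate patient identifier {dup_rows[0]!r}")
    dup_cols = df.columns[df.columns.duplicated()]
    if len(dup_cols):
        raise ValueError(f"{path}: duplicate feature identifier {dup_cols[0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at "
            f"patient {df.index[i]!r}, feature {df.columns[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    return OmicsLayer(
        name=name,
        patients=list(df.index),
        features=list(df.columns),
        values=values,
        mask=mask,
    )


def filter_missing(
    layer: OmicsLayer,
    patient_max_missing: float = 0.2,
    feature_max_missing: float = 0.2,
) -> OmicsLayer:
    """Drop patients then features with too much missingness; impute the rest.

    A patient is removed when strictly more than ``patient_max_missing`` of
    its entries are missing; afterwards a feature is removed when strictly
    more than ``feature_max_missing`` of its entries (over the surviving
    patients) are missing.  Fractions exactly at the threshold are kept.
    Residual missing entries are imputed with the feature mean of the
    observed values, so the returned layer is complete.
    """
    for thr in (patient_max_missing, feature_max_missing):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("missingness thresholds must lie in [0, 1]")
    missing = ~layer.mask
    patient_frac = missing.mean(axis=1)
    keep_p = patient_frac <= patient_max_missing
    if not keep_p.any():
        raise ValueError(f"layer {layer.name!r}: every patient exceeds the missingness threshold")
    missing = missing[keep_p]
    feature_frac = missing.mean(axis=0)
    keep_f = feature_frac <= feature_max_missing
    if not keep_f.any():
        raise ValueError(f"layer {layer.name!r}: every feature exceeds the missingness threshold")

    values = layer.values[np.ix_(keep_p, keep_f)].copy()
    mask = layer.mask[np.ix_(keep_p, keep_f)]
    if not mask.all():
        n_imputed = int((~mask).sum())
        logger.info("layer %s: imputing %d residual missing entries with feature means",
                    layer.name, n_imputed)
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(np.where(mask, values, np.nan), axis=0)
        col_means = np.nan_to_num(col_means)  # unreachable unless threshold is 1.0
        rr, cc = np.nonzero(~mask)
        values[rr, cc] = col_means[cc]
    return OmicsLayer(
        name=layer.name,
        patients=[p for p, k in zip(layer.patients, keep_p) if k],
        features=[f for f, k in zip(layer.features, keep_f) if k],
        values=values,
        mask=np.ones_like(values, dtype=bool),
        normalized=layer.normalized,
    )


def normalize_layer(layer: OmicsLayer, sd_convention: str = "sd") -> OmicsLayer:
    """Standardize every feature to mean zero and unit spread.

    ``sd_convention="sd"`` (the default) divides centered features by the
    population standard deviation (ddof=0), giving classical z-scores and the
    unit-variance geometry the Euclidean kernels downstream expect.
    ``sd_convention="variance"`` divides by the variance instead, for anyone
    wanting the literal mean/variance normalization reading.  Zero-variance
    features carry no between-patient information and are dropped with a
    logged warning.
    """
    if sd_convention not in ("sd", "variance"):
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    if not layer.complete:
        raise ValueError(f"layer {layer.name!r} still has missing entries; run filter_missing first")
    values = layer.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    keep = sd > 0.0
    if not keep.all():
        dropped = [f for f, k in zip(layer.features, keep) if not k]
        logger.warning("layer %s: dropping %d zero-variance feature(s): %s%s",
                       layer.name, len(dropped), ", ".join(dropped[:5]),
                       "..." if len(dropped) > 5 else "")
    scale = sd if sd_convention == "sd" else sd**2
    normed = (values[:, keep] - mean[keep]) / scale[keep]
    return OmicsLayer(
        name=layer.name,
        patients=list(layer.patients),
        features=[f for f, k in zip(layer.features, keep) if k],
        values=normed,
        mask=np.ones_like(normed, dtype=bool),
        normalized=True,
    )


def intersect_cohort(
    layers: list[OmicsLayer],
    clinical: pd.DataFrame | None = None,
) -> CohortBundle:
    """Restrict all layers (and the clinical table) to their shared patients.

    The resulting patient ordering follows the first layer's order.  Raises
    with per-layer cohort sizes if the intersection is empty.
    """
    if not layers:
        raise ValueError("need at least one layer")
    common = set(layers[0].patients)
    for layer in layers[1:]:
        common &= set(layer.patients)
    if clinical is not None:
        common &= set(map(str, clinical.index))
    if not common:
        sizes = ", ".join(f"{l.name}: {l.n_patients}" for l in layers)
        raise ValueError(f"no patients shared across all inputs (layer sizes: {sizes})")
    ordered = [p for p in layers[0].patients if p in common]
    out_layers = [layer.subset_patients(ordered) for layer in layers]
    out_clin = clinical.loc[ordered].copy() if clinical is not None else None
    return CohortBundle(layers=out_layers, clinical=out_clin)


def shift_rescale(layer: OmicsLayer) -> OmicsLayer:
    """Translate values to be non-negative, then rescale into [0, 1].

    If the matrix minimum is negative its absolute value is added to every
    entry; the matrix is then divided by its maximum.  Provided for parity
    with non-negative matrix factorization preprocessing; the main pipeline
    uses z-scored features instead.
    """
    values = layer.values.copy()
    mn = values.min()
    if mn < 0:
        values = values - mn
    mx = values.max()
    if mx == values.min():
        raise ValueError(f"layer {layer.name!r}: constant matrix, rescaling undefined")
    values = values / mx
    return OmicsLayer(
        name=layer.name,
        patients=list(layer.patients),
        features=list(layer.features),
        values=values,
        mask=layer.mask.copy(),
        normalized=False,
    )
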