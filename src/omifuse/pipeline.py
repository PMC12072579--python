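"""End-to-end orchestration: files -> preprocessing -> fusion -> subtypes.

Two entry points:

* :func:`subtype_cohort` - the programmatic pipeline on an in-memory
  :class:`~omifuse.preprocess.CohortBundle` (used by tests and scripts).
* :func:`run_pipeline` - the file-driven pipeline behind the CLI: loads
  layer TSVs per a :class:`RunConfig`, runs the full procedure, and writes
  labels, weights, the integrated matrix, the silhouette-by-k table, a
  validity-metric summary, and a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity import pairwise_euclidean, scaled_exponential_affinity
from .clustering import SubtypeResult, affinity_to_distance, select_k
from .fusion import IntegratedAffinity, integrate
from .metrics import calinski_harabasz, davies_bouldin, silhouette
from .preprocess import (CohortBundle, filter_missing, intersect_cohort,
                         load_layer, normalize_layer)
from .wnn import WeightMatrix, cohort_weights

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineOutput", "subtype_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Defaults pin the method's conventional settings: KNN and kernel
    neighborhoods of 20, kernel scale 0.5, ratio guard 1e-8, candidate
    cluster counts 2..10, and 1000 consensus iterations at an 80% subsample.
    """

    layer_paths: dict[str, str] = field(default_factory=dict)  # name -> path
    clinical_path: str | None = None
    orientation: str = "rows-are-patients"
    patient_max_missing: float = 0.2
    feature_max_missing: float = 0.2
    sd_convention: str = "sd"
    knn_k: int = 20
    affinity_K: int = 20
    affinity_mu: float = 0.5
    epsilon: float = 1e-8
    k: int | None = None          # fixed cluster count; None = select by silhouette
    k_min: int = 2
    k_max: int = 10
    reps: int = 1000
    subsample_fraction: float = 0.8
    silhouette_substrate: str = "features"  # or "integrated"
    seed: int = 0
    outdir: str = "omifuse_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def validate_paths(self) -> None:
        if not self.layer_paths:
            raise ValueError("config lists no omics layers")
        for name, p in self.layer_paths.items():
            if not Path(p).is_file():
                raise FileNotFoundError(f"layer {name!r}: file not found: {p}")
        if self.clinical_path is not None and not Path(self.clinical_path).is_file():
            raise FileNotFoundError(f"clinical file not found: {self.clinical_path}")


@dataclass
class PipelineOutput:
    bundle: CohortBundle
    weights: WeightMatrix
    integrated: IntegratedAffinity
    result: SubtypeResult
    metrics: pd.DataFrame


def subtype_cohort(
    bundle: CohortBundle,
    knn_k: int = 20,
    affinity_K: int = 20,
    affinity_mu: float = 0.5,
    epsilon: float = 1e-8,
    k: int | None = None,
    k_min: int = 2,
    k_max: int = 10,
    reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    sd_convention: str = "sd",
    silhouette_substrate: str = "features",
) -> PipelineOutput:
    """Run preprocessing-to-subtypes on an in-memory cohort bundle.

    Layers that are not yet normalized are missingness-filtered,
    re-intersected and standardized first.  When ``k`` is given the
    silhouette scan is restricted to that single value (the user override).
    ``silhouette_substrate`` chooses the space for cluster-count selection:
    ``"features"`` (concatenated standardized layers, the default) or
    ``"integrated"`` (the fused 1 - a distance).
    """
    if silhouette_substrate not in ("features", "integrated"):
        raise ValueError(f"unknown silhouette_substrate {silhouette_substrate!r}")
    layers = bundle.layers
    if not all(l.normalized for l in layers):
        layers = [filter_missing(l) for l in layers]
        bundle = intersect_cohort(layers, bundle.clinical)
        layers = [normalize_layer(l, sd_convention=sd_convention) for l in bundle.layers]
        bundle = CohortBundle(layers=layers, clinical=bundle.clinical)

    t0 = time.perf_counter()
    affinities = [
        scaled_exponential_affinity(pairwise_euclidean(l), K=affinity_K,
                                    mu=affinity_mu, omics=l.name)
        for l in bundle.layers
    ]
    weights = cohort_weights(bundle, k=knn_k, epsilon=epsilon)
    integrated = integrate(affinities, weights)
    logger.info("affinity/weights/fusion: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    concat = np.hstack([l.values for l in bundle.layers])
    lo, hi = (k, k) if k is not None else (k_min, k_max)
    result = select_k(
        integrated, k_min=lo, k_max=hi, reps=reps,
        subsample_fraction=subsample_fraction, seed=seed, weights=weights,
        features=concat if silhouette_substrate == "features" else None,
    )
    logger.info("consensus clustering (k in [%d, %d]): %.2fs",
                lo, hi, time.perf_counter() - t0)

    d = affinity_to_distance(integrated).d
    metrics = pd.DataFrame([{
        "k": result.k,
        "silhouette_integrated": silhouette(d, result.labels, metric="precomputed"),
        "davies_bouldin": davies_bouldin(concat, result.labels),
        "calinski_harabasz": calinski_harabasz(concat, result.labels),
    }])
    return PipelineOutput(bundle=bundle, weights=weights, integrated=integrated,
                          result=result, metrics=metrics)


def run_pipeline(config: RunConfig) -> PipelineOutput:
    """Load files per ``config``, run the pipeline, and write all artifacts."""
    config.validate_paths()
    layers = [
        load_layer(path, name=name, orientation=config.orientation)
        for name, path in config.layer_paths.items()
    ]
    layers = [
        filter_missing(l, config.patient_max_missing, config.feature_max_missing)
        for l in layers
    ]
    clinical = None
    if config.clinical_path is not None:
        clinical = pd.read_csv(config.clinical_path, sep=None, engine="python",
                               index_col=0)
        clinical.index = clinical.index.map(str)
    bundle = intersect_cohort(layers, clinical)
    bundle = CohortBundle(
        layers=[normalize_layer(l, sd_convention=config.sd_convention)
                for l in bundle.layers],
        clinical=bundle.clinical,
    )
    out = subtype_cohort(
        bundle,
        knn_k=config.knn_k, affinity_K=config.affinity_K,
        affinity_mu=config.affinity_mu, epsilon=config.epsilon,
        k=config.k, k_min=config.k_min, k_max=config.k_max,
        reps=config.reps, subsample_fraction=config.subsample_fraction,
        seed=config.seed, sd_convention=config.sd_convention,
        silhouette_substrate=config.silhouette_substrate,
    )
    _write_outputs(out, config)
    return out


def _write_outputs(out: PipelineOutput, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out.result.labels_frame().to_csv(outdir / "labels.tsv", sep="\t", index=False)
    out.weights.write_tsv(outdir / "weights.tsv")
    out.integrated.write_tsv(outdir / "integrated_affinity.tsv")
    out.result.silhouette_by_k.to_csv(outdir / "silhouette_by_k.tsv", sep="\t",
                                      index=False)
    out.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    if out.result.per_subtype_weight_medians is not None:
        out.result.per_subtype_weight_medians.to_csv(
            outdir / "subtype_weight_medians.tsv", sep="\t"
        )
    import sklearn
    import scipy
    manifest = {
        "config": asdict(config),
        "versions": {
            "omifuse": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "n_patients": len(out.bundle.patients),
        "chosen_k": out.result.k,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
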