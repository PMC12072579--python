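"""Synthetic multi-omics cohorts with known subtype structure.

The generator emulates the features of real multi-omics cohorts the
pipeline relies on: several layers over one patient set, each a Gaussian
noise matrix on which a configurable fraction of "informative" features
carries subtype-specific mean shifts (in units of the noise SD, so signal
strength is comparable across layers), optional missingness applied
uniformly at random, and subtype-dependent exponential survival with
exponential censoring calibrated to a target censoring rate.  Informative
features are partitioned across subtypes in a one-hot block design: each
subtype elevates its own block of features, which yields cleanly separable
Euclidean geometry - the structure the integration pipeline assumes.

Everything is driven by a single seed, so cohorts are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocess import CohortBundle, OmicsLayer

__all__ = [
    "LayerSpec",
    "SimulationSpec",
    "simulate_cohort",
    "simulate_uninformative_layer",
    "write_cohort",
]


@dataclass
class LayerSpec:
    """Configuration of one simulated omics layer.

    signal_strength is the subtype mean shift in units of noise_sd applied
    to a signal_fraction of the features; strength 0 makes the layer pure
    noise.
    """

    name: str
    n_features: int = 200
    signal_strength: float = 3.0
    signal_fraction: float = 0.2
    noise_sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort.

    Defaults describe the reference scenario used throughout the test
    suite: 120 patients in three equally sized subtypes, two layers of 200
    features with 3-SD shifts on 20% of features, unit noise, no
    missingness, subtype hazards (0.02, 0.05, 0.1) per unit time and 20%
    censoring.
    """

    n_patients: int = 120
    n_subtypes: int = 3
    subtype_proportions: tuple[float, ...] | None = None
    layers: list[LayerSpec] = field(default_factory=lambda: [
        LayerSpec(name="mRNA"),
        LayerSpec(name="methylation"),
    ])
    hazards: tuple[float, ...] | None = None
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple([1.0 / self.n_subtypes] * self.n_subtypes)
        if len(self.subtype_proportions) != self.n_subtypes:
            raise ValueError("one proportion per subtype required")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if any(p < 0 for p in self.subtype_proportions):
            raise ValueError("proportions must be nonnegative")
        if self.hazards is None:
            base = np.geomspace(0.02, 0.1, self.n_subtypes)
            self.hazards = tuple(float(h) for h in base)
        if len(self.hazards) != self.n_subtypes:
            raise ValueError("one hazard per subtype required")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not self.layers:
            raise ValueError("need at least one layer spec")


def _subtype_sizes(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of n patients to subtypes."""
    raw = np.asarray(proportions) * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    if (sizes == 0).any():
        raise ValueError("a subtype would receive zero patients; adjust proportions or n")
    return sizes


def _layer_values(
    spec: LayerSpec,
    labels: np.ndarray,
    n_subtypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(labels)
    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    n_inf = int(round(spec.signal_fraction * spec.n_features))
    if n_inf == 0 or spec.signal_strength == 0.0:
        return values
    # one-hot block design: subtype s elevates its own block of features
    blocks = np.array_split(np.arange(n_inf), n_subtypes)
    shift = spec.signal_strength * spec.noise_sd
    for s, feats in enumerate(blocks, start=1):
        if len(feats):
            values[np.ix_(labels == s, feats)] += shift
    return values


def _censoring_hazard(
    hazards: tuple[float, ...],
    sizes: np.ndarray,
    target: float,
) -> float:
    """Exponential censoring hazard c with P(censored) = target overall.

    For an Exp(lambda) event time and independent Exp(c) censoring time the
    censoring probability is c / (lambda + c); the cohort-level rate is the
    size-weighted mixture, solved for c by bisection.
    """
    w = sizes / sizes.sum()

    def frac(c: float) -> float:
        return float(sum(wi * c / (h + c) for wi, h in zip(w, hazards))) - target

    hi = max(hazards) * target / (1 - target) * 10 + 1.0
    while frac(hi) < 0:
        hi *= 10
    return brentq(frac, 1e-12, hi)


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[CohortBundle, np.ndarray, pd.DataFrame]:
    """Generate a cohort bundle, true subtype labels, and a survival table.

    Returns ``(bundle, labels, survival)`` where ``labels`` are the true
    subtype ids in 1..n_subtypes and ``survival`` has columns
    ``time``/``event``/``subtype`` indexed by patient id.  Layer values are
    raw (not normalized); missing entries are NaN with the mask unset.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _subtype_sizes(spec.n_patients, spec.subtype_proportions)
    labels = np.repeat(np.arange(1, spec.n_subtypes + 1), sizes)
    width = len(str(spec.n_patients))
    patients = [f"P{i + 1:0{width}d}" for i in range(spec.n_patients)]

    layers = []
    for lspec in spec.layers:
        values = _layer_values(lspec, labels, spec.n_subtypes, rng)
        mask = np.ones_like(values, dtype=bool)
        if lspec.missing_rate > 0:
            mask = rng.random(values.shape) >= lspec.missing_rate
            values = np.where(mask, values, np.nan)
        feats = [f"{lspec.name}_f{j + 1}" for j in range(lspec.n_features)]
        layers.append(OmicsLayer(
            name=lspec.name, patients=patients, features=feats,
            values=values, mask=mask,
        ))

    event_scale = 1.0 / np.asarray(spec.hazards)[labels - 1]
    t_event = rng.exponential(event_scale)
    if spec.censoring_rate > 0:
        c = _censoring_hazard(spec.hazards, sizes, spec.censoring_rate)
        t_cens = rng.exponential(1.0 / c, size=spec.n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(spec.n_patients, dtype=int)
    survival = pd.DataFrame(
        {"time": time, "event": event, "subtype": labels},
        index=pd.Index(patients, name="patient"),
    )
    bundle = CohortBundle(layers=layers, clinical=survival[["time", "event"]].copy())
    return bundle, labels, survival


def simulate_uninformative_layer(
    n_patients: int,
    n_features: int,
    seed: int,
    noise_sd: float = 1.0,
    name: str = "noise",
) -> OmicsLayer:
    """Pure Gaussian noise layer (no subtype structure at all)."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(n_patients, n_features))
    width = len(str(n_patients))
    return OmicsLayer(
        name=name,
        patients=[f"P{i + 1:0{width}d}" for i in range(n_patients)],
        features=[f"{name}_f{j + 1}" for j in range(n_features)],
        values=values,
        mask=np.ones_like(values, dtype=bool),
    )


def write_cohort(
    bundle: CohortBundle,
    labels: np.ndarray,
    survival: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a simulated cohort as the TSV files the loaders read back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for layer in bundle.layers:
        p = outdir / f"{layer.name}.tsv"
        layer.to_frame().to_csv(p, sep="\t", index_label="patient")
        paths[layer.name] = p
    surv_path = outdir / "clinical.tsv"
    survival.to_csv(surv_path, sep="\t")
    paths["clinical"] = surv_path
    lab_path = outdir / "true_labels.tsv"
    pd.DataFrame({"patient": bundle.patients, "subtype": labels}).to_csv(
        lab_path, sep="\t", index=False
    )
    paths["true_labels"] = lab_path
    return paths
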