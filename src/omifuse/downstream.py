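"""Subtype characterization: survival separation, signature scores, drug hints.

These utilities operate on the subtype labels produced by the integration
pipeline plus standard clinical/expression side tables:

* :func:`logrank_test` - k-sample log-rank comparison of overall survival
  across subtypes (delegates to lifelines).
* :func:`signature_scores` - rank-based gene-signature scoring: each gene's
  expression is converted to a percentile rank across samples, the ranks
  are averaged over the signature's genes, and the average is re-expressed
  as a percentile across samples.  Being rank-based, the scores are
  invariant to any monotone per-gene transformation.
* :func:`recommend_drugs` - for inhibitor/antagonist drugs, recommend a
  drug to a subtype whenever at least one of its target genes is
  upregulated there (two-sided Wilcoxon rank-sum of subtype vs rest with
  p < alpha, direction decided by the median difference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import mannwhitneyu, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "logrank_test",
    "read_gmt",
    "signature_scores",
    "recommend_drugs",
]


@dataclass
class SignatureSet:
    """A named, non-empty gene list (case-sensitive identifiers)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")


def logrank_test(survival: pd.DataFrame) -> tuple[float, int, float]:
    """(k-1)-df log-rank test of survival differences across subtypes.

    ``survival`` needs columns ``time`` (nonnegative follow-up), ``event``
    (1 = death observed, 0 = censored) and ``subtype``.  Returns
    ``(chi2_statistic, degrees_of_freedom, p_value)``.
    """
    for col in ("time", "event", "subtype"):
        if col not in survival.columns:
            raise ValueError(f"survival table is missing column {col!r}")
    if survival["subtype"].isna().any():
        raise ValueError("every patient needs a subtype label")
    if (survival["time"] < 0).any():
        raise ValueError("negative follow-up time")
    if not set(np.unique(survival["event"])) <= {0, 1}:
        raise ValueError("event indicator must be 0 or 1")
    groups = survival["subtype"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two subtypes")
    if int(survival["event"].sum()) == 0:
        raise ValueError("all observations censored: log-rank test undefined")
    res = multivariate_logrank_test(
        survival["time"], survival["subtype"], survival["event"]
    )
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def read_gmt(path: str | Path) -> list[SignatureSet]:
    """Read GMT-format gene sets (name, description, genes... per line)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(SignatureSet(name=parts[0], genes=[g for g in parts[2:] if g]))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def _percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-rank percentile of each entry among the column's values, in [0, 100]."""
    return rankdata(values, method="average") / len(values) * 100.0


def signature_scores(
    expr: pd.DataFrame,
    sets: list[SignatureSet],
) -> pd.DataFrame:
    """Samples x signatures percentile scores from normalized expression.

    ``expr`` is samples x genes, already normalized to a comparable
    log scale.  Unmatched signature genes are dropped with a warning; a set
    with no matched genes is an error.
    """
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    gene_ranks = expr.apply(lambda col: _percentile_ranks(col.to_numpy()), axis=0)
    out = {}
    for sig in sets:
        matched = [g for g in sig.genes if g in expr.columns]
        missing = set(sig.genes) - set(matched)
        if not matched:
            raise ValueError(f"signature {sig.name!r}: none of its genes are in the expression matrix")
        if missing:
            logger.warning("signature %s: dropping %d unmatched gene(s)",
                           sig.name, len(missing))
        avg_rank = gene_ranks[matched].mean(axis=1).to_numpy()
        out[sig.name] = _percentile_ranks(avg_rank)
    return pd.DataFrame(out, index=expr.index)


def recommend_drugs(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    targets: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subtype drug recommendations from target-gene upregulation.

    ``targets`` needs columns ``drug``, ``gene``, ``mechanism``; only
    inhibitor/antagonist rows are considered.  For every subtype and target
    gene present in ``expr`` (samples x genes), a two-sided Wilcoxon
    rank-sum test compares the subtype against all other samples; the gene
    counts as upregulated when p < alpha and the subtype median exceeds the
    rest's median.  A drug is recommended for each subtype in which at
    least one of its targets is upregulated.  Returns a table with one row
    per (subtype, drug, gene) piece of supporting evidence; empty when
    nothing is significant.
    """
    for col in ("drug", "gene", "mechanism"):
        if col not in targets.columns:
            raise ValueError(f"drug-target table is missing column {col!r}")
    labels = np.asarray(labels)
    if labels.shape[0] != expr.shape[0]:
        raise ValueError("label vector length does not match the expression matrix")
    mech = targets["mechanism"].str.lower()
    actionable = targets[mech.isin(["inhibitor", "antagonist"])]
    if actionable.duplicated(["drug", "gene"]).any():
        raise ValueError("duplicate (drug, gene) pairs in the target table")
    genes = [g for g in actionable["gene"].unique() if g in expr.columns]
    skipped = set(actionable["gene"].unique()) - set(genes)
    if skipped:
        logger.warning("skipping %d target gene(s) absent from expression: %s",
                       len(skipped), ", ".join(sorted(skipped)[:5]))
    rows = []
    for subtype in np.unique(labels):
        in_grp = labels == subtype
        if in_grp.sum() < 2 or (~in_grp).sum() < 2:
            logger.warning("subtype %r has fewer than 2 patients; skipped", subtype)
            continue
        for gene in genes:
            x = expr.loc[in_grp, gene].to_numpy()
            y = expr.loc[~in_grp, gene].to_numpy()
            stat, p = mannwhitneyu(x, y, alternative="two-sided")
            if p < alpha and np.median(x) > np.median(y):
                for drug in actionable.loc[actionable["gene"] == gene, "drug"]:
                    rows.append({
                        "subtype": subtype,
                        "drug": drug,
                        "gene": gene,
                        "p_value": float(p),
                        "subtype_median": float(np.median(x)),
                        "rest_median": float(np.median(y)),
                    })
    cols = ["subtype", "drug", "gene", "p_value", "subtype_median", "rest_median"]
    return pd.DataFrame(rows, columns=cols)
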