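"""Normalization chain and fold-change computation.

The pipeline order is fixed: per-sample quantile normalization, per-gene
z-score, then signed logarithmic scaling. Each operation refuses input at
the wrong stage. Fold changes are computed on the *raw* matrix (ratios of
arithmetic condition means to the control mean).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import CONTROL_ARM, ExpressionSet, condition_label
from .errors import DataValidationError

__all__ = [
    "quantile_normalize",
    "zscore_genes",
    "signed_log_scale",
    "fold_changes",
    "collapse_probes",
    "FoldChangeTable",
]


def quantile_normalize(es: ExpressionSet) -> ExpressionSet:
    """Force every sample column onto the mean empirical distribution.

    The reference distribution is the mean of the per-column sorted value
    vectors. Ties within a column receive the mean of the reference values
    their rank span covers, so rank order is preserved and tied entries
    stay tied.
    """
    es.require_stage("raw")
    if es.n_samples < 2:
        raise DataValidationError("quantile normalization needs >= 2 samples")
    x = es.values
    reference = np.sort(x, axis=0).mean(axis=1)
    cumref = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        rmin = rankdata(col, method="min").astype(np.int64)
        rmax = rankdata(col, method="max").astype(np.int64)
        out[:, j] = (cumref[rmax] - cumref[rmin - 1]) / (rmax - rmin + 1)
    return es.with_values(out, "quantile")


def zscore_genes(es: ExpressionSet) -> ExpressionSet:
    """Per-gene z-score (sample sd, ddof=1); constant rows map to zeros."""
    es.require_stage("quantile")
    if es.n_samples < 2:
        raise DataValidationError("z-scoring needs >= 2 samples")
    x = es.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    centered = x - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return es.with_values(z, "zscored")


def signed_log_scale(es: ExpressionSet) -> ExpressionSet:
    """x -> sign(x) * ln(1 + |x|): sign-, rank- and monotonicity-preserving."""
    es.require_stage("zscored")
    x = es.values
    return es.with_values(np.sign(x) * np.log1p(np.abs(x)), "logscaled")


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold changes of condition means vs the control mean.

    ``log2fc`` is gene x condition (control column absent). ``arm_max``
    returns, per arm, the signed entry of greatest magnitude across the
    arm's doses (the "greatest fold change across the dose series"
    convention).
    """

    log2fc: pd.DataFrame
    arms: dict[str, list[str]]  # arm -> its condition labels

    def arm_max(self, arm: str) -> pd.Series:
        cols = self.arms[arm]
        block = self.log2fc[cols].to_numpy()
        pick = np.abs(block).argmax(axis=1)
        signed = block[np.arange(block.shape[0]), pick]
        return pd.Series(signed, index=self.log2fc.index, name=f"max_log2fc_{arm}")

    def arm_max_abs(self, arm: str) -> pd.Series:
        return self.arm_max(arm).abs().rename(f"max_abs_log2fc_{arm}")


def fold_changes(es: ExpressionSet) -> FoldChangeTable:
    """log2(mean(condition)/mean(control)) per gene and non-control condition."""
    es.require_stage("raw")
    cond_idx = es.condition_indices()
    if CONTROL_ARM not in cond_idx:
        raise DataValidationError("control condition absent from design")
    control_mean = es.values[:, cond_idx[CONTROL_ARM]].mean(axis=1)
    cols = {}
    arms: dict[str, list[str]] = {}
    for label, idx in cond_idx.items():
        if label == CONTROL_ARM:
            continue
        cond_mean = es.values[:, idx].mean(axis=1)
        cols[label] = np.log2(cond_mean / control_mean)
        arm = label.rsplit("-", 1)[0]
        arms.setdefault(arm, []).append(label)
    table = pd.DataFrame(cols, index=es.genes)
    return FoldChangeTable(log2fc=table, arms=arms)


def collapse_probes(es: ExpressionSet, probe_to_gene: dict[str, str]) -> ExpressionSet:
    """Optional ingest helper: keep, per gene, the probe of maximal raw variance.

    Rows absent from the map are kept under their own identifier.
    """
    es.require_stage("raw")
    variances = es.values.var(axis=1, ddof=1)
    best: dict[str, int] = {}
    for i, probe in enumerate(es.genes):
        gene = probe_to_gene.get(probe, probe)
        if gene not in best or variances[i] > variances[best[gene]]:
            best[gene] = i
    genes = sorted(best)
    rows = [best[g] for g in genes]
    return ExpressionSet(
        genes=genes,
        design=es.design.copy(),
        values=es.values[rows, :],
        stage="raw",
    )
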