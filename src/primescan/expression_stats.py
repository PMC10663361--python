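"""Count normalisation, expressed/not-expressed calls, multiple-testing
correction and a simple internal differential-expression fallback.

Expression is worked with in counts-per-million (CPM); the expressed /
not-expressed boundary is mean CPM >= 9 across a stage's replicates. The
internal DE method is a deliberately simple stand-in — Welch t-test on
log2(CPM + 0.5) with Benjamini-Hochberg adjustment — for use when no
externally computed DE table (e.g., limma-voom output) is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionTable

__all__ = [
    "DEResult",
    "cpm",
    "is_expressed",
    "bh_adjust",
    "bonferroni_adjust",
    "simple_de",
    "EXPRESSED_CPM_THRESHOLD",
    "PSEUDO_CPM",
]

EXPRESSED_CPM_THRESHOLD = 9.0
PSEUDO_CPM = 0.5


@dataclass(frozen=True)
class DEResult:
    """Differential expression of one gene between two stages (S2 vs S1)."""

    gene_id: str
    stage_pair: tuple[str, str]
    log2fc: float
    pvalue: float
    padj: float
    method: str  # "external" | "internal_ttest"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"{self.gene_id}: pvalue {self.pvalue} outside [0, 1]")


def cpm(table: ExpressionTable) -> ExpressionTable:
    """Counts-per-million: ``1e6 * count / column_sum`` per sample."""
    sums = table.df.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return ExpressionTable(1e6 * table.df / sums)


def is_expressed(
    gene_id: str,
    stage: str,
    cpm_table: ExpressionTable,
    threshold: float = EXPRESSED_CPM_THRESHOLD,
    rule: str = "mean",
) -> bool:
    """Expressed iff mean CPM across the stage's replicates >= threshold.

    ``rule="all"`` instead requires every replicate to clear the
    threshold (the stricter per-replicate reading of the CPM cutoff).
    """
    if gene_id not in cpm_table.df.index:
        raise KeyError(f"unknown gene {gene_id!r}")
    vals = cpm_table.stage_values(stage).loc[gene_id]
    if rule == "mean":
        return bool(vals.mean() >= threshold)
    if rule == "all":
        return bool((vals >= threshold).all())
    raise ValueError(f"unknown rule {rule!r}")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni: ``min(1, p * m)`` with a caller-chosen family size m."""
    p = np.asarray(pvalues, dtype=float)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m < p.size:
        raise ValueError(f"m = {m} is smaller than the number of tests ({p.size})")
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


def simple_de(table: ExpressionTable, s1: str, s2: str) -> list[DEResult]:
    """Internal DE fallback: Welch t-test on log2(CPM + 0.5), BH-adjusted.

    log2fc is computed from stage-mean CPM with the same 0.5 pseudo-CPM.
    Genes with zero variance in both stages get p = 1 when the means are
    equal and p = 0 otherwise (the degenerate exact rule). Requires >= 2
    replicates per stage; supply an external DE table otherwise.
    """
    cpm_table = cpm(table)
    x1 = cpm_table.stage_values(s1)
    x2 = cpm_table.stage_values(s2)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError(
            f"simple_de needs >= 2 replicates per stage (got {x1.shape[1]} for "
            f"{s1}, {x2.shape[1]} for {s2}); supply an external DE table instead"
        )
    l1 = np.log2(x1.values + PSEUDO_CPM)
    l2 = np.log2(x2.values + PSEUDO_CPM)
    log2fc = np.log2(x2.values.mean(axis=1) + PSEUDO_CPM) - np.log2(
        x1.values.mean(axis=1) + PSEUDO_CPM
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(l2, l1, axis=1, equal_var=False)
    # zero variance in both groups -> nan from the t-test; exact rule
    degenerate = np.isnan(pvals)
    if degenerate.any():
        equal_means = np.isclose(l1.mean(axis=1), l2.mean(axis=1))
        pvals = np.where(degenerate, np.where(equal_means, 1.0, 0.0), pvals)
    padj = bh_adjust(pvals)
    return [
        DEResult(g, (s1, s2), float(log2fc[i]), float(pvals[i]), float(padj[i]),
                 "internal_ttest")
        for i, g in enumerate(cpm_table.genes)
    ]
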