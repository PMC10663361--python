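"""Enhancer RNA summaries and VEGF-responsiveness classification.

eRNA transcription at intergenic primed elements is summarised as the
per-stage median of per-element Z-scores of CPM-normalised RNA tag
counts. VEGF-responsive primed elements are those whose open-chromatin
presence depends on the VEGF condition: open with VEGF withdrawn
(minus_VEGF) but closed under the full cytokine mix (all_cytokines) —
the direction in which VEGF withdrawal primes the hematopoietic fate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .expression_stats import PSEUDO_CPM, bonferroni_adjust
from .genomic_core import GeneAnnotation, GenomicInterval, find_overlaps

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionPeakPresence",
    "classify_intergenic",
    "erna_zscores",
    "classify_vegf_responsive",
    "vegf_gene_report",
    "CONDITIONS",
]

CONDITIONS = ("all_cytokines", "minus_VEGF")


@dataclass(frozen=True)
class ConditionPeakPresence:
    """Open-chromatin presence of one element under each culture condition."""

    peak_id: str
    stage: str
    presence: tuple[tuple[str, bool], ...]  # ((condition, present), ...)

    def __post_init__(self) -> None:
        if not self.presence:
            raise ValueError("at least one condition must be recorded")
        for cond, _ in self.presence:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")


def classify_intergenic(
    elements: Mapping[str, GenomicInterval], genes: Sequence[GeneAnnotation]
) -> tuple[list[str], list[str]]:
    """Partition elements into (intergenic, intragenic) by gene-body overlap."""
    eids = sorted(elements)
    hits = find_overlaps([elements[e] for e in eids], [g.body for g in genes])
    intragenic_idx = {qi for qi, _ in hits}
    intergenic = [e for i, e in enumerate(eids) if i not in intragenic_idx]
    intragenic = [e for i, e in enumerate(eids) if i in intragenic_idx]
    return intergenic, intragenic


def erna_zscores(
    counts: pd.DataFrame,
    stage_order: Sequence[str],
    library_sizes: Mapping[str, float] | None = None,
) -> pd.Series:
    """Per-stage median Z-score of eRNA tag counts at intergenic elements.

    ``counts`` is element x stage (RNA fragments overlapping each element
    per stage). Counts are CPM-normalised against per-stage library sizes
    (column sums by default), log2(+0.5)-transformed, standardised per
    element across stages (constant elements contribute zeros), and the
    median across elements is taken per stage.
    """
    stages = list(stage_order)
    missing = [s for s in stages if s not in counts.columns]
    if missing:
        raise ValueError(f"missing stage count column(s): {missing}")
    sub = counts[stages].astype(float)
    if library_sizes is None:
        totals = sub.sum(axis=0)
    else:
        totals = pd.Series({s: float(library_sizes[s]) for s in stages})
    if (totals <= 0).any():
        raise ValueError("non-positive library size")
    cpm = 1e6 * sub / totals
    logv = np.log2(cpm + PSEUDO_CPM)
    sd = logv.std(axis=1, ddof=0)
    z = logv.sub(logv.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z[sd == 0] = 0.0
    return z.median(axis=0)


def classify_vegf_responsive(
    primed_elements: Mapping[str, GenomicInterval],
    minus_vegf_peaks: Sequence[GenomicInterval],
    all_cytokines_peaks: Sequence[GenomicInterval],
) -> tuple[list[str], list[str]]:
    """Split primed elements by VEGF-condition presence.

    Returns ``(responsive, opposite)``: responsive elements overlap a
    minus_VEGF peak and no all_cytokines peak (VEGF withdrawal opens
    them); opposite-direction elements overlap only the all_cytokines
    set. Elements open in both or neither are in neither list.
    """
    if minus_vegf_peaks is None or all_cytokines_peaks is None:
        raise ValueError("both condition peak sets are required")
    eids = sorted(primed_elements)
    queries = [primed_elements[e] for e in eids]
    in_minus = {qi for qi, _ in find_overlaps(queries, list(minus_vegf_peaks))}
    in_all = {qi for qi, _ in find_overlaps(queries, list(all_cytokines_peaks))}
    responsive = [e for i, e in enumerate(eids) if i in in_minus and i not in in_all]
    opposite = [e for i, e in enumerate(eids) if i in in_all and i not in in_minus]
    return responsive, opposite


def vegf_gene_report(
    responsive_genes: Sequence[str],
    expr_minus: pd.DataFrame,
    expr_plus: pd.DataFrame,
    m: int | None = None,
    external_pvalues: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Fold change and Bonferroni-corrected p per gene linked to a
    VEGF-responsive element.

    ``expr_minus`` / ``expr_plus`` are gene x replicate expression tables
    for the minus_VEGF and all_cytokines conditions. Fold change is the
    ratio of condition means (-VEGF over +VEGF). P-values come from a
    Welch t-test across replicates unless ``external_pvalues`` supplies
    them; Bonferroni uses ``m`` (default: number of genes reported).
    Genes missing from either table are logged and skipped.
    """
    genes = sorted(set(responsive_genes))
    rows = []
    for g in genes:
        if g not in expr_minus.index or g not in expr_plus.index:
            logger.warning("gene %s missing from condition expression; skipped", g)
            continue
        a = expr_minus.loc[g].astype(float).values
        b = expr_plus.loc[g].astype(float).values
        if b.mean() == 0:
            fc = 1.0 if a.mean() == 0 else float("inf")
        else:
            fc = float(a.mean() / b.mean())
        if external_pvalues is not None and g in external_pvalues:
            p = float(external_pvalues[g])
        elif np.allclose(a, a.mean()) and np.allclose(b, b.mean()):
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            p = float(sp_stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append((g, fc, p))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "fold_change", "pvalue", "p_bonferroni"]
                            ).set_index("gene_id")
    df = pd.DataFrame(rows, columns=["gene_id", "fold_change", "pvalue"]
                      ).set_index("gene_id")
    m_eff = m if m is not None else len(df)
    df["p_bonferroni"] = bonferroni_adjust(df["pvalue"].values, m_eff)
    return df
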