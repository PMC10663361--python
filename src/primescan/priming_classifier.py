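"""Classification of primed enhancer elements across stage transitions.

A primed enhancer at transition S1 -> S2 is a distal element (> 1.5 kb
from any TSS) that tests enhancer-positive at both S1 and S2, whose
linked gene (promoter-capture Hi-C where available, nearest gene
otherwise) is not expressed at S1 (CPM < 9) and is significantly
up-regulated at S2 (log2 fold change >= 1, adjusted p < 0.05). Each
primed element also carries a dynamics class describing how its
reporter activity state changed across the transition.

Stage-specific peaks are first merged into reference elements by
single-linkage >=1 bp overlap, which makes "occurring in both stages"
well-defined when peak boundaries differ between stages.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_stats import (
    DEResult,
    EXPRESSED_CPM_THRESHOLD,
    PSEUDO_CPM,
    is_expressed,
)
from .genomic_core import (
    GeneAnnotation,
    GenomicInterval,
    UnassignableError,
    distance_to_nearest_tss,
    find_overlaps,
    nearest_gene,
)
from .io_formats import ExpressionTable, InteractionLink
from .screen_activity import EnhancerCall

logger = logging.getLogger(__name__)

__all__ = [
    "PrimedRecord",
    "StageOrder",
    "DEFAULT_STAGES",
    "DISTAL_MIN_BP",
    "merge_elements",
    "aggregate_element_calls",
    "link_peak_to_gene",
    "classify_primed",
    "dynamics_class",
    "persistence",
    "median_expression_zscore",
    "multiplicity_per_gene",
]

DEFAULT_STAGES = ("ES", "HB", "HE", "HP")  # HE is the HE1 dataset
DISTAL_MIN_BP = 1500
DYNAMICS_CLASSES = ("High>High", "Low>Low", "Low>High", "High>Low")


@dataclass(frozen=True)
class PrimedRecord:
    """One primed element x transition x linked gene."""

    peak_id: str
    transition: tuple[str, str]
    gene_id: str
    link_method: str  # "chic" | "nearest"
    state_s1: str
    state_s2: str
    dynamics: str

    def __post_init__(self) -> None:
        if self.link_method not in ("chic", "nearest"):
            raise ValueError(f"link_method must be chic|nearest, got {self.link_method!r}")
        if self.dynamics not in DYNAMICS_CLASSES:
            raise ValueError(f"unknown dynamics class {self.dynamics!r}")


class StageOrder:
    """An ordered tuple of stage labels; transitions are consecutive pairs."""

    def __init__(self, stages: Sequence[str] = DEFAULT_STAGES):
        stages = tuple(stages)
        if len(stages) < 2:
            raise ValueError("need at least two stages")
        if len(set(stages)) != len(stages):
            raise ValueError("stage labels must be unique")
        self.stages = stages

    @property
    def transitions(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    def later_than(self, stage: str) -> list[str]:
        i = self.stages.index(stage)
        return list(self.stages[i + 1:])

    def __iter__(self):
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)


# ---------------------------------------------------------------------------
# Reference elements


def merge_elements(
    peaks_per_stage: Mapping[str, Mapping[str, GenomicInterval]],
) -> tuple[dict[str, GenomicInterval], dict[str, dict[str, list[str]]]]:
    """Merge stage-specific peaks into reference elements.

    Single-linkage: any two peaks (from any stages) sharing >= 1 bp land
    in the same element, whose interval is the union span. Returns
    ``(elements, membership)`` where ``membership[element_id][stage]`` is
    the list of constituent peak ids. Element ids are ``elem_00001`` ...
    in (chrom, start) order.
    """
    flat: list[tuple[str, str, GenomicInterval]] = []
    for stage in sorted(peaks_per_stage):
        for pid in sorted(peaks_per_stage[stage]):
            flat.append((stage, pid, peaks_per_stage[stage][pid]))
    flat.sort(key=lambda t: (t[2].chrom, t[2].start, t[2].end, t[0], t[1]))

    clusters: list[list[tuple[str, str, GenomicInterval]]] = []
    cur_chrom, cur_end = None, -1
    for stage, pid, iv in flat:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            clusters[-1].append((stage, pid, iv))
            cur_end = max(cur_end, iv.end)
        else:
            clusters.append([(stage, pid, iv)])
            cur_chrom, cur_end = iv.chrom, iv.end
    elements: dict[str, GenomicInterval] = {}
    membership: dict[str, dict[str, list[str]]] = {}
    for i, cluster in enumerate(clusters, start=1):
        eid = f"elem_{i:05d}"
        chrom = cluster[0][2].chrom
        start = min(iv.start for _, _, iv in cluster)
        end = max(iv.end for _, _, iv in cluster)
        elements[eid] = GenomicInterval(chrom, start, end)
        memb: dict[str, list[str]] = {}
        for stage, pid, _ in cluster:
            memb.setdefault(stage, []).append(pid)
        membership[eid] = memb
    return elements, membership


def aggregate_element_calls(
    membership: Mapping[str, Mapping[str, list[str]]],
    calls_per_stage: Mapping[str, Mapping[str, EnhancerCall]],
    activity_ratio: float = 1.0,
) -> dict[str, dict[str, EnhancerCall]]:
    """Lift per-peak calls onto reference elements, per stage.

    Fragment counts and normalised counts of an element's constituent
    peaks are summed; the element is positive if any constituent peak is,
    and its state follows the summed normalised high:low comparison
    (ties to Low, as for single peaks).
    """
    out: dict[str, dict[str, EnhancerCall]] = {}
    for stage in sorted(calls_per_stage):
        stage_calls = calls_per_stage[stage]
        out[stage] = {}
        for eid in sorted(membership):
            pids = membership[eid].get(stage, [])
            calls = [stage_calls[p] for p in pids if p in stage_calls]
            nh = sum(c.n_high for c in calls)
            nl = sum(c.n_low for c in calls)
            if nh + nl >= 1:
                norm_h = sum(c.norm_high for c in calls)
                norm_l = sum(c.norm_low for c in calls)
                state = "High" if norm_h > activity_ratio * norm_l else "Low"
                out[stage][eid] = EnhancerCall(
                    eid, stage, True, nh, nl, norm_h, norm_l, state
                )
            else:
                out[stage][eid] = EnhancerCall(
                    eid, stage, False, 0, 0, 0.0, 0.0, "NotPositive"
                )
    return out


# ---------------------------------------------------------------------------
# Peak-to-gene linking


def link_peak_to_gene(
    peak: GenomicInterval,
    interactions: Sequence[InteractionLink],
    genes: Sequence[GeneAnnotation],
) -> tuple[str, str]:
    """Assign a peak to a gene: CHi-C other-end overlap first, else nearest.

    Among overlapping interactions the highest-score one wins (missing
    scores rank lowest; ties break to the lexicographically smallest bait
    gene). Raises :class:`UnassignableError` if the nearest-gene fallback
    finds no gene on the peak's chromosome.
    """
    hits = find_overlaps([peak], [l.other_end for l in interactions])
    if hits:
        best: tuple[float, str] | None = None
        for _, j in hits:
            link = interactions[j]
            score = link.score if link.score is not None else float("-inf")
            # maximise score, then minimise gene_id
            cand = (-score, link.bait_gene)
            if best is None or cand < best:
                best = cand
        return best[1], "chic"
    return nearest_gene(peak, genes), "nearest"


# ---------------------------------------------------------------------------
# The priming classifier


def dynamics_class(state_s1: str, state_s2: str) -> str:
    """Map the (S1, S2) activity-state pair to its dynamics label."""
    for s in (state_s1, state_s2):
        if s not in ("High", "Low"):
            raise ValueError(f"dynamics requires High/Low states, got {s!r}")
    return f"{state_s1}>{state_s2}"


def classify_primed(
    transition: tuple[str, str],
    element_calls: Mapping[str, Mapping[str, EnhancerCall]],
    elements: Mapping[str, GenomicInterval],
    genes: Sequence[GeneAnnotation],
    links: Sequence[InteractionLink],
    cpm_table: ExpressionTable,
    de_results: Sequence[DEResult],
    distal_min_bp: int = DISTAL_MIN_BP,
    cpm_threshold: float = EXPRESSED_CPM_THRESHOLD,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
    expressed_rule: str = "mean",
) -> list[PrimedRecord]:
    """Emit a :class:`PrimedRecord` for every element passing all gates.

    Gates, in order: (1) distal — distance to nearest TSS strictly
    greater than ``distal_min_bp``; (2) enhancer-positive at both S1 and
    S2; (3) linked gene not expressed at S1 (mean CPM below
    ``cpm_threshold``); (4) DE S1 -> S2 with log2fc >= ``lfc_min`` and
    padj < ``padj_max`` ("twofold up-regulation", inclusive boundary).
    """
    s1, s2 = transition
    if s1 not in element_calls or s2 not in element_calls:
        raise ValueError(f"missing enhancer calls for transition {s1}->{s2}")
    de_pair = {r.gene_id: r for r in de_results if r.stage_pair == (s1, s2)}
    if not de_pair:
        raise ValueError(f"no DE results supplied for stage pair {s1}->{s2}")

    records: list[PrimedRecord] = []
    for eid in sorted(elements):
        call1 = element_calls[s1].get(eid)
        call2 = element_calls[s2].get(eid)
        if call1 is None or call2 is None or not (call1.positive and call2.positive):
            continue
        peak = elements[eid]
        try:
            dist, _ = distance_to_nearest_tss(peak, genes)
        except UnassignableError:
            logger.warning("element %s: no gene on %s; dropped", eid, peak.chrom)
            continue
        if dist <= distal_min_bp:
            continue
        try:
            gene_id, method = link_peak_to_gene(peak, links, genes)
        except UnassignableError:
            logger.warning("element %s: unassignable; dropped", eid)
            continue
        if gene_id not in cpm_table.df.index:
            logger.warning("element %s: linked gene %s absent from expression; dropped",
                           eid, gene_id)
            continue
        if is_expressed(gene_id, s1, cpm_table, cpm_threshold, expressed_rule):
            continue
        de = de_pair.get(gene_id)
        if de is None or not (de.log2fc >= lfc_min and de.padj < padj_max):
            continue
        records.append(
            PrimedRecord(
                peak_id=eid,
                transition=(s1, s2),
                gene_id=gene_id,
                link_method=method,
                state_s1=call1.state,
                state_s2=call2.state,
                dynamics=dynamics_class(call1.state, call2.state),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Summary statistics


def persistence(
    primed: Sequence[PrimedRecord],
    element_calls: Mapping[str, Mapping[str, EnhancerCall]],
    stage_order: StageOrder,
) -> dict[str, float]:
    """Percentage of elements primed at S1 still enhancer-positive at each
    later stage. Empty primed set -> empty result."""
    if not primed:
        return {}
    s1 = primed[0].transition[0]
    if any(r.transition[0] != s1 for r in primed):
        raise ValueError("primed records span multiple transitions")
    element_ids = sorted({r.peak_id for r in primed})
    out: dict[str, float] = {}
    for stage in stage_order.later_than(s1):
        calls = element_calls.get(stage, {})
        n_pos = sum(1 for e in element_ids if e in calls and calls[e].positive)
        out[stage] = 100.0 * n_pos / len(element_ids)
    return out


def _stage_log_cpm(cpm_table: ExpressionTable, stages: Sequence[str]) -> pd.DataFrame:
    """Per-gene, per-stage mean of log2(CPM + 0.5) over replicates."""
    cols = {s: np.log2(cpm_table.stage_values(s) + PSEUDO_CPM).mean(axis=1)
            for s in stages}
    return pd.DataFrame(cols)


def median_expression_zscore(
    gene_ids: Sequence[str],
    cpm_table: ExpressionTable,
    stage_order: StageOrder,
) -> pd.Series:
    """Per-stage median of per-gene expression Z-scores.

    Each gene's mean log2(CPM + 0.5) profile is standardised across the
    stage axis (population mean 0, sd 1); genes constant across stages
    contribute all-zero profiles. The median over the gene set is then
    taken per stage.
    """
    stages = list(stage_order)
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    gene_ids = sorted(set(gene_ids))
    missing = [g for g in gene_ids if g not in cpm_table.df.index]
    if missing:
        raise KeyError(f"genes absent from expression table: {missing}")
    prof = _stage_log_cpm(cpm_table, stages).loc[gene_ids]
    sd = prof.std(axis=1, ddof=0)
    centred = prof.sub(prof.mean(axis=1), axis=0)
    z = centred.div(sd.where(sd > 0, 1.0), axis=0)
    z[sd == 0] = 0.0
    return z.median(axis=0)


def multiplicity_per_gene(primed: Sequence[PrimedRecord]) -> pd.Series:
    """Primed-element count per linked gene (histogram-ready)."""
    counts = Counter(r.gene_id for r in primed)
    return pd.Series(dict(sorted(counts.items())), dtype=int)
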