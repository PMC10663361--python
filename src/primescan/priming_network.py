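"""Construction of the stage-transition priming gene-regulatory network.

Nodes are TF families (all motifs sharing a family label collapse to one
node) and primed target genes. An edge F -> G exists when a motif of
family F has a hit in a primed element linked to G and at least one
member gene of F is expressed (CPM >= 9) at the first stage of the
transition. Rebuilding the network with the second stage's expression
and diffing the two shows how motif usage changes upon activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .expression_stats import EXPRESSED_CPM_THRESHOLD, is_expressed
from .genomic_core import GeneAnnotation
from .io_formats import ExpressionTable
from .priming_classifier import PrimedRecord

__all__ = ["PrimingNetwork", "build_network", "count_primed_tf_genes", "network_delta"]


@dataclass
class PrimingNetwork:
    """TF-family -> gene edges carried by primed elements, for one transition."""

    graph: nx.DiGraph
    transition: tuple[str, str]
    elements: frozenset[str] = field(default_factory=frozenset)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())


def _mean_stage_cpm(cpm_table: ExpressionTable, gene: str, stage: str) -> float:
    if gene not in cpm_table.df.index:
        return 0.0
    return float(cpm_table.stage_values(stage).loc[gene].mean())


def build_network(
    primed: Sequence[PrimedRecord],
    motif_matrix: pd.DataFrame,
    tf_catalog: Mapping[str, tuple[str, Sequence[str]]],
    cpm_table: ExpressionTable,
    transition: tuple[str, str],
    expressed_threshold: float = EXPRESSED_CPM_THRESHOLD,
    expression_stage: str | None = None,
) -> PrimingNetwork:
    """Build the priming network for one transition.

    ``motif_matrix`` is the binary element x motif matrix; every motif
    column hit in a primed element must be present in ``tf_catalog``
    (motif_id -> (family, member gene ids)). ``expression_stage``
    defaults to S1 (the priming stage); pass S2 to rebuild the
    post-activation network for :func:`network_delta`.
    """
    s1, s2 = transition
    stage = expression_stage if expression_stage is not None else s1
    g = nx.DiGraph()
    primed_elements = sorted({r.peak_id for r in primed})
    missing = [e for e in primed_elements if e not in motif_matrix.index]
    if missing:
        raise ValueError(f"motif annotation missing for primed elements: {missing}")

    def family_expressed(members: Sequence[str]) -> bool:
        return any(
            m in cpm_table.df.index
            and is_expressed(m, stage, cpm_table, expressed_threshold)
            for m in members
        )

    gene_of = {}
    for r in primed:
        gene_of.setdefault(r.peak_id, set()).add(r.gene_id)

    for eid in primed_elements:
        row = motif_matrix.loc[eid]
        for motif_id in motif_matrix.columns[row.values.astype(bool)]:
            if motif_id not in tf_catalog:
                raise KeyError(f"motif {motif_id!r} hit in element {eid} is absent "
                               f"from the TF catalog")
            family, members = tf_catalog[motif_id]
            if not family_expressed(members):
                continue
            fam_expr_s1 = max((_mean_stage_cpm(cpm_table, m, s1) for m in members),
                              default=0.0)
            fam_expr_s2 = max((_mean_stage_cpm(cpm_table, m, s2) for m in members),
                              default=0.0)
            g.add_node(family, kind="tf_family", expression_s1=fam_expr_s1,
                       expression_s2=fam_expr_s2, primed=False)
            for gene in sorted(gene_of[eid]):
                g.add_node(
                    gene, kind="gene",
                    expression_s1=_mean_stage_cpm(cpm_table, gene, s1),
                    expression_s2=_mean_stage_cpm(cpm_table, gene, s2),
                    primed=True,
                )
                if g.has_edge(family, gene):
                    g.edges[family, gene]["carried_by"].add(eid)
                else:
                    g.add_edge(family, gene, carried_by={eid},
                               transition=f"{s1}>{s2}")
    return PrimingNetwork(g, transition, frozenset(primed_elements))


def count_primed_tf_genes(
    primed: Sequence[PrimedRecord], genes: Sequence[GeneAnnotation]
) -> int:
    """Number of distinct primed target genes that encode TFs."""
    tf_ids = {g.gene_id for g in genes if g.is_tf}
    return len({r.gene_id for r in primed} & tf_ids)


def network_delta(
    net_s1: PrimingNetwork, net_s2: PrimingNetwork
) -> dict[str, object]:
    """Edge gain/loss between the priming-stage and post-activation networks.

    Both networks must cover the same primed-element universe (and the
    same transition). Returns sorted edge lists present only at S1, only
    at S2, and shared, plus per-node expression changes (S2 minus S1
    mean CPM) for nodes present in either network.
    """
    if net_s1.transition != net_s2.transition:
        raise ValueError("networks belong to different transitions")
    if net_s1.elements != net_s2.elements:
        raise ValueError("mismatched element universes between the two networks")
    e1, e2 = net_s1.edges, net_s2.edges
    nodes = set(net_s1.graph.nodes()) | set(net_s2.graph.nodes())
    expr_change = {}
    for n in sorted(nodes):
        d = (net_s2.graph.nodes[n] if n in net_s2.graph else net_s1.graph.nodes[n])
        expr_change[n] = d.get("expression_s2", 0.0) - d.get("expression_s1", 0.0)
    return {
        "only_s1": sorted(e1 - e2),
        "only_s2": sorted(e2 - e1),
        "shared": sorted(e1 & e2),
        "expression_change": expr_change,
    }
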