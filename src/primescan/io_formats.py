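"""Readers and writers for the on-disk formats the pipeline touches.

Everything is strict: malformed lines raise with a line number, duplicate
gene ids raise, coordinate violations raise. Readers never silently skip
data. Writers are byte-stable for identical input (sorted output, fixed
numeric formatting at 6 significant digits).

Formats handled: BED3/BED6, 6-column BEDPE (collapsed to a single span),
FASTA element sequences, JASPAR-style PWM text, TSV count matrices,
promoter-capture Hi-C link tables, external DE tables, gene annotation
tables, TF catalogs, and SIF + GraphML + node-attribute TSV exports of
the priming network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomic_core import GeneAnnotation, GenomicInterval

if TYPE_CHECKING:  # pragma: no cover
    from .priming_network import PrimingNetwork

__all__ = [
    "FragmentRecord",
    "ExpressionTable",
    "InteractionLink",
    "PWMotif",
    "LIBRARY_LABELS",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_expression",
    "write_expression",
    "read_pwms",
    "write_pwms",
    "read_fasta",
    "write_fasta",
    "read_links",
    "write_links",
    "read_de_table",
    "write_de_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_tf_catalog",
    "write_tf_catalog",
    "write_network",
    "fmt6",
]

LIBRARY_LABELS = ("plasmid", "negative_control", "sorted_high", "sorted_low")

BASES = "ACGT"


class ParseError(ValueError):
    """A malformed input file; carries the offending path and line number."""


def fmt6(x: float) -> str:
    """Format a number at 6 significant digits (byte-stable writer output)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"


@dataclass(frozen=True)
class FragmentRecord:
    """One reporter-screen fragment: a genomic span plus its library of origin."""

    interval: GenomicInterval
    library: str
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.library not in LIBRARY_LABELS:
            raise ValueError(
                f"library must be one of {LIBRARY_LABELS}, got {self.library!r}"
            )


@dataclass(frozen=True)
class InteractionLink:
    """A promoter-capture Hi-C link: bait gene promoter to a distal other end."""

    bait_gene: str
    other_end: GenomicInterval
    score: float | None = None


@dataclass
class PWMotif:
    """A position weight matrix: per-position base probabilities over ACGT.

    ``threshold`` is the log-odds score cutoff in bits; ``None`` means the
    scanner's default fraction-of-maximum rule applies.
    """

    motif_id: str
    tf_family: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: matrix length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(
                f"{self.motif_id}: position probabilities must sum to 1 (got {sums})"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]


class ExpressionTable:
    """A gene x sample count (or CPM) matrix with (stage, replicate) samples.

    Sample labels follow the convention ``STAGE_repN``. Backed by a pandas
    DataFrame whose columns are the raw sample labels, with the parsed
    (stage, replicate) keys kept alongside.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate gene_id(s): {dups}")
        self.df = df.astype(float)
        self.samples: list[tuple[str, int]] = [
            _parse_sample_label(c) for c in df.columns
        ]

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for stage, _ in self.samples:
            if stage not in seen:
                seen.append(stage)
        return seen

    def stage_columns(self, stage: str) -> list[str]:
        cols = [c for c, (s, _) in zip(self.df.columns, self.samples) if s == stage]
        if not cols:
            raise KeyError(f"unknown stage {stage!r}")
        return cols

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.df[self.stage_columns(stage)]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionTable) and self.df.equals(other.df)


def _parse_sample_label(label: str) -> tuple[str, int]:
    stage, sep, rep = label.rpartition("_rep")
    if not sep or not rep.isdigit() or not stage:
        raise ParseError(
            f"sample label {label!r} does not follow the STAGE_repN convention"
        )
    return stage, int(rep)


# ---------------------------------------------------------------------------
# BED / BEDPE


def _parse_bed_line(fields: list[str], path: str, ln: int) -> GenomicInterval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:{ln}: malformed BED line: {exc}") from exc
    strand = "."
    if len(fields) >= 6 and fields[5] in ("+", "-"):
        strand = fields[5]
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise ParseError(f"{path}:{ln}: {exc}") from exc


def _is_bedpe(fields: list[str]) -> bool:
    # BED6 carries a strand symbol in column 6; BEDPE carries mate-2
    # coordinates (chrom2, int, int) in columns 4-6.
    if len(fields) < 6:
        return False
    try:
        int(fields[4]), int(fields[5])
    except ValueError:
        return False
    return fields[3] not in ("+", "-", ".")


def read_bed(
    path: str | Path,
    library: str | None = None,
    stage: str | None = None,
    deduplicate: bool = True,
) -> list[FragmentRecord] | list[GenomicInterval]:
    """Read a BED3/BED6 (or 6-column BEDPE) file.

    With ``library`` set, returns deduplicated :class:`FragmentRecord`
    objects (identical chrom/start/end within a library collapse to one,
    mirroring uniq-style duplicate-fragment removal); otherwise returns
    raw :class:`GenomicInterval` objects in file order.

    BEDPE mate pairs are collapsed to the min-start/max-end span; mates on
    different chromosomes are an error.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{ln}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            if _is_bedpe(fields):
                iv1 = _parse_bed_line(fields[:3], str(path), ln)
                iv2 = _parse_bed_line(fields[3:6], str(path), ln)
                if iv1.chrom != iv2.chrom:
                    raise ParseError(
                        f"{path}:{ln}: BEDPE mates on different chromosomes "
                        f"({iv1.chrom} vs {iv2.chrom})"
                    )
                intervals.append(
                    GenomicInterval(
                        iv1.chrom, min(iv1.start, iv2.start), max(iv1.end, iv2.end)
                    )
                )
            else:
                intervals.append(_parse_bed_line(fields, str(path), ln))
    if library is None:
        return intervals
    records: list[FragmentRecord] = []
    seen: set[tuple[str, int, int]] = set()
    for iv in intervals:
        if deduplicate:
            if iv.key in seen:
                continue
            seen.add(iv.key)
        records.append(FragmentRecord(iv, library, stage))
    return records


def write_bed(
    path: str | Path,
    items: Iterable[GenomicInterval | FragmentRecord],
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals (or fragment records) as BED3, or BED6 with names."""
    items = list(items)
    ivs = [it.interval if isinstance(it, FragmentRecord) else it for it in items]
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a TSV count matrix: first column gene_id, headers ``STAGE_repN``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate gene_id(s): {dups}")
    for col in df.columns:
        _parse_sample_label(col)
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric count(s) in column {col!r}: "
                f"{bad.iloc[0]!r} at gene {bad.index[0]!r}"
            )
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts present")
    return ExpressionTable(df)


def write_expression(path: str | Path, table: ExpressionTable) -> None:
    df = table.df.copy()
    out = df.map(fmt6)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PWMs (JASPAR-style text)


def read_pwms(path: str | Path, pseudocount: float = 1.0) -> list[PWMotif]:
    """Read a JASPAR-style PWM file.

    Blocks are ``>motif_id tf_family`` followed by four base rows
    (``A [ 3 5 ... ]`` or ``A 3 5 ...``). Count matrices are converted to
    probabilities with a pseudocount: ``p = (n + pc) / (colsum + 4 pc)``.
    A block whose columns already sum to ~1 is taken as probabilities and
    left unchanged.
    """
    path = Path(path)
    motifs: list[PWMotif] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def flush(ln: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(BASES):
            raise ParseError(
                f"{path}:{ln}: motif {header[0]} missing base rows "
                f"{sorted(set(BASES) - set(rows))}"
            )
        lengths = {b: len(rows[b]) for b in BASES}
        if len(set(lengths.values())) != 1:
            raise ParseError(
                f"{path}:{ln}: motif {header[0]} has unequal row lengths {lengths}"
            )
        mat = np.array([rows[b] for b in BASES], dtype=float).T  # (L, 4)
        colsums = mat.sum(axis=1)
        if np.allclose(colsums, 1.0, atol=0.01):
            mat = mat / colsums[:, None]
        else:
            mat = (mat + pseudocount) / (colsums + 4 * pseudocount)[:, None]
        motifs.append(PWMotif(header[0], header[1], mat))
        header, rows = None, {}

    with open(path) as fh:
        ln = 0
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(ln)
                parts = line[1:].split(None, 1)
                motif_id = parts[0]
                family = parts[1].strip() if len(parts) > 1 else motif_id
                header = (motif_id, family)
            else:
                if header is None:
                    raise ParseError(f"{path}:{ln}: matrix row before any > header")
                base, _, rest = line.partition(" ")
                base = base.upper()
                if base not in BASES:
                    raise ParseError(f"{path}:{ln}: unknown base row {base!r}")
                if base in rows:
                    raise ParseError(f"{path}:{ln}: duplicate base row {base!r}")
                vals = rest.replace("[", " ").replace("]", " ").split()
                try:
                    rows[base] = [float(v) for v in vals]
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: bad number: {exc}") from exc
        flush(ln + 1)
    return motifs


def write_pwms(path: str | Path, motifs: Iterable[PWMotif]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.tf_family}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.6f}" for v in m.matrix[:, bi])
                fh.write(f"{base} {vals}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Element id -> uppercase DNA sequence."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Link tables, DE tables, gene annotation, TF catalog (all TSV)


def read_links(path: str | Path) -> list[InteractionLink]:
    """TSV with columns bait_gene, chrom, start, end[, score]."""
    df = pd.read_csv(path, sep="\t")
    required = {"bait_gene", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: link table needs columns {sorted(required)}")
    links = []
    for row in df.itertuples(index=False):
        score = float(row.score) if "score" in df.columns and pd.notna(row.score) else None
        links.append(
            InteractionLink(
                str(row.bait_gene),
                GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                score,
            )
        )
    return links


def write_links(path: str | Path, links: Iterable[InteractionLink]) -> None:
    with open(path, "w") as fh:
        fh.write("bait_gene\tchrom\tstart\tend\tscore\n")
        for l in links:
            score = fmt6(l.score) if l.score is not None else ""
            fh.write(
                f"{l.bait_gene}\t{l.other_end.chrom}\t{l.other_end.start}"
                f"\t{l.other_end.end}\t{score}\n"
            )


def read_de_table(path: str | Path):
    """External DE results: gene_id, stage1, stage2, log2fc, pvalue, padj."""
    from .expression_stats import DEResult

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "stage1", "stage2", "log2fc", "pvalue", "padj"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: DE table needs columns {sorted(required)}")
    return [
        DEResult(
            gene_id=str(r.gene_id),
            stage_pair=(str(r.stage1), str(r.stage2)),
            log2fc=float(r.log2fc),
            pvalue=float(r.pvalue),
            padj=float(r.padj),
            method="external",
        )
        for r in df.itertuples(index=False)
    ]


def write_de_table(path: str | Path, results) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstage1\tstage2\tlog2fc\tpvalue\tpadj\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.stage_pair[0]}\t{r.stage_pair[1]}\t"
                f"{fmt6(r.log2fc)}\t{fmt6(r.pvalue)}\t{fmt6(r.padj)}\n"
            )


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """TSV: gene_id, symbol, chrom, start, end, strand, tss, is_tf."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "symbol", "chrom", "start", "end", "strand", "tss", "is_tf"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dups = sorted(df["gene_id"][df["gene_id"].duplicated()])
        raise ParseError(f"{path}: duplicate gene_id(s): {dups}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            symbol=str(r.symbol),
            tss=int(r.tss),
            body=GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
            strand=str(r.strand),
            is_tf=bool(r.is_tf),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_annotation(path: str | Path, genes: Iterable[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstart\tend\tstrand\ttss\tis_tf\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.body.chrom}\t{g.body.start}\t"
                f"{g.body.end}\t{g.strand}\t{g.tss}\t{int(g.is_tf)}\n"
            )


def read_tf_catalog(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """TSV: motif_id, tf_family, member_genes (comma-separated gene ids)."""
    df = pd.read_csv(path, sep="\t")
    required = {"motif_id", "tf_family", "member_genes"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: TF catalog needs columns {sorted(required)}")
    catalog: dict[str, tuple[str, list[str]]] = {}
    for r in df.itertuples(index=False):
        members = [m for m in str(r.member_genes).split(",") if m]
        catalog[str(r.motif_id)] = (str(r.tf_family), members)
    return catalog


def write_tf_catalog(path: str | Path, catalog: Mapping[str, tuple[str, list[str]]]) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttf_family\tmember_genes\n")
        for motif_id in sorted(catalog):
            family, members = catalog[motif_id]
            fh.write(f"{motif_id}\t{family}\t{','.join(members)}\n")


# ---------------------------------------------------------------------------
# Network export (SIF + node-attribute TSV + GraphML)


def write_network(network: "PrimingNetwork", path_prefix: str | Path) -> list[Path]:
    """Export a priming network as SIF, node-attribute TSV and GraphML.

    The SIF relation is ``motif``. Node attributes cover every node that
    appears in an edge (and isolated nodes, if any). Output is sorted and
    therefore byte-stable. Empty networks yield empty-but-valid files.
    """
    prefix = Path(path_prefix)
    g = network.graph
    sif_path = prefix.with_suffix(".sif")
    nodes_path = Path(str(prefix) + "_nodes.tsv")
    graphml_path = prefix.with_suffix(".graphml")

    with open(sif_path, "w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\tmotif\t{v}\n")

    with open(nodes_path, "w") as fh:
        fh.write("node\tkind\texpression_s1\texpression_s2\tprimed\n")
        for n in sorted(g.nodes()):
            d = g.nodes[n]
            fh.write(
                f"{n}\t{d.get('kind', '')}\t{fmt6(d.get('expression_s1', 0.0))}\t"
                f"{fmt6(d.get('expression_s2', 0.0))}\t{int(d.get('primed', False))}\n"
            )

    # GraphML via networkx; lists are not GraphML-serialisable, join them.
    g2 = nx.DiGraph()
    for n in sorted(g.nodes()):
        d = dict(g.nodes[n])
        d["primed"] = int(d.get("primed", False))
        g2.add_node(n, **d)
    for u, v in sorted(g.edges()):
        d = dict(g.edges[u, v])
        if "carried_by" in d:
            d["carried_by"] = ",".join(sorted(d["carried_by"]))
        g2.add_edge(u, v, **d)
    nx.write_graphml(g2, graphml_path)
    return [sif_path, nodes_path, graphml_path]
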