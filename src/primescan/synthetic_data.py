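"""Synthetic dataset generator with planted ground truth.

Emulates the full input bundle of the priming analysis with no
downloads: five-to-four ordered stages of an in vitro differentiation
(ES, HB, HE, HP by default, HE standing for the HE1 dataset), per-stage
ATAC peaks opening and closing, sorted high/low reporter fragment
libraries contaminated with artefacts absent from the plasmid library,
RNA-seq count matrices in which planted primed genes sit below the CPM-9
expressed threshold at the priming stage and rise at least the
configured fold at the next stage, promoter-capture Hi-C links for a
subset of elements (the rest exercise the nearest-gene fallback), motif
consensi planted in element sequences, ChIP-like feature peak sets, and
±VEGF condition-specific peaks at the final transition.

The genome is laid out as one gene locus per 20 kb: the gene body
occupies the first 5 kb, and the locus's element (if any) sits 8 kb
(intergenic) or 3 kb (intragenic) downstream of the TSS — always more
than 1.5 kb away, so every element is distal by construction.

Every draw flows from one seeded generator; the same seed yields a
byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic_core import GeneAnnotation, GenomicInterval
from . import io_formats as io
from .io_formats import (
    ExpressionTable,
    FragmentRecord,
    InteractionLink,
    PWMotif,
    fmt6,
)

__all__ = ["SimulationConfig", "GroundTruth", "EvalResult", "simulate", "evaluate",
           "builtin_motifs"]

import pandas as pd

LOCUS_SPAN = 20_000
GENE_BODY_LEN = 5_000
ELEMENT_LEN = 500
INTERGENIC_OFFSET = 8_000
INTRAGENIC_OFFSET = 3_000

# role labels for elements
PRIMED, ACTIVE, SINGLE_STAGE, SILENT_GENE, NONPOSITIVE = (
    "primed", "active", "single_stage", "silent_gene", "nonpositive"
)

_BUILTIN_CONSENSI = [
    ("M_RUNX", "RUNX", "TGTGGTTT"),
    ("M_ETS", "ETS", "ACAGGAAGT"),
    ("M_GATA", "GATA", "AGATAAGG"),
    ("M_SOX", "SOX", "CTTTGTTC"),
    ("M_OCT", "OCT", "ATGCAAAT"),
    ("M_SMAD", "SMAD", "GTCTAGAC"),
    ("M_TEAD", "TEAD", "ACATTCCA"),
    ("M_AP1", "AP1", "TGACTCAG"),
]
# families whose member TFs are expressed at every stage (safe donors for
# the first planted motif of a primed element)
_EARLY_FAMILIES = ("ETS", "SOX", "OCT", "SMAD", "TEAD", "AP1")
_LATE_FAMILIES = ("RUNX", "GATA")


def builtin_motifs(consensus_prob: float = 0.85) -> list[PWMotif]:
    """The default synthetic motif set: one sharp PWM per TF family."""
    motifs = []
    for motif_id, family, consensus in _BUILTIN_CONSENSI:
        L = len(consensus)
        mat = np.full((L, 4), (1 - consensus_prob) / 3)
        for i, base in enumerate(consensus):
            mat[i, "ACGT".index(base)] = consensus_prob
        motifs.append(PWMotif(motif_id, family, mat))
    return motifs


@dataclass
class SimulationConfig:
    """The stated world of the generator; defaults match the desk-scale
    acceptance bundle (seed 7, 400 elements, 40 planted primed pairs per
    transition, 5% artefact rate)."""

    seed: int = 7
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 1_000
    tf_fraction: float = 0.1
    n_elements: int = 400
    primed_fraction: float = 0.1  # per transition
    stages: tuple[str, ...] = ("ES", "HB", "HE", "HP")
    replicates: int = 4
    fragment_depth: int = 20  # sorted fragments per positive element-stage
    artefact_rate: float = 0.05  # screen fragments absent from plasmid
    negative_contamination_rate: float = 0.02
    n_background_fragments: int = 200
    chic_fraction: float = 0.5
    vegf_responsive_fraction: float = 0.5
    intragenic_fraction: float = 0.5
    persistence_prob: float = 0.7
    high_fragment_prob: float = 0.8  # P(high library | true High element)
    baseline_log2_cpm: float = 9.0
    baseline_log2_cpm_sd: float = 2.0
    dispersion: float = 0.05  # NB: var = mu + disp * mu^2
    primed_low_cpm: tuple[float, float] = (2.0, 5.0)
    primed_fold_change: float = 16.0  # must be >= 2
    # 20M reads emulates a realistic bulk RNA-seq library: with the gene
    # catalog scaled down ~20x from a full transcriptome, this keeps the
    # per-gene read depth (and hence count noise near the CPM-9 line) at
    # real-data levels.
    library_size: int = 20_000_000
    condition_replicates: int = 6
    noiseless: bool = False

    def __post_init__(self) -> None:
        for name in ("primed_fraction", "tf_fraction", "artefact_rate",
                     "negative_contamination_rate", "chic_fraction",
                     "vegf_responsive_fraction", "intragenic_fraction",
                     "persistence_prob", "high_fragment_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        self.stages = tuple(self.stages)
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")
        if self.primed_fold_change < 2.0:
            raise ValueError("primed_fold_change must be >= 2 (the twofold gate)")
        if int(self.primed_fraction * self.n_elements) < 1:
            raise ValueError(
                "infeasible config: primed_fraction * n_elements < 1 "
                "(no primed pair can be planted)"
            )
        if self.n_elements > self.n_genes:
            raise ValueError("need at least one gene locus per element")
        capacity = self.n_chromosomes * (self.chrom_length // LOCUS_SPAN)
        if capacity < self.n_genes:
            raise ValueError(
                f"genome too small: {capacity} loci available for {self.n_genes} genes"
            )

    @property
    def transitions(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    @property
    def n_primed_per_transition(self) -> int:
        return int(self.primed_fraction * self.n_elements)


@dataclass
class GroundTruth:
    """Planted truth, consistent with every generated file."""

    primed_pairs: dict[str, list[tuple[str, str]]]  # "S1>S2" -> (element, gene)
    states: dict[str, dict[str, str]]  # stage -> element -> High|Low
    positive: dict[str, list[str]]  # stage -> positive element ids
    motif_content: dict[str, list[str]]  # element -> planted motif ids
    vegf_responsive: list[str]
    vegf_opposite: list[str]
    expressed_tfs: dict[str, list[str]]  # stage -> expressed TF gene ids
    element_gene: dict[str, str]  # element -> host gene
    element_role: dict[str, str]
    element_transition: dict[str, str]  # "" for roleless assignments

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["primed_pairs"] = {k: [list(p) for p in v]
                             for k, v in self.primed_pairs.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["primed_pairs"] = {k: [tuple(p) for p in v]
                             for k, v in d["primed_pairs"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: float,
             noiseless: bool) -> np.ndarray:
    if noiseless:
        return np.rint(mu).astype(int)
    mu = np.maximum(mu, 1e-9)
    n = 1.0 / disp
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _unique_fragment(rng: np.random.Generator, chrom: str, lo: int, hi: int,
                     seen: set, min_len: int = 200, max_len: int = 450):
    """A fragment span inside [lo, hi) not seen before (rejection sampled)."""
    for _ in range(1000):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(lo, max(lo + 1, hi - length)))
        key = (chrom, start, start + length)
        if key not in seen:
            seen.add(key)
            return GenomicInterval(chrom, start, start + length)
    raise RuntimeError("could not draw a unique fragment (region too small)")


def simulate(config: SimulationConfig, out_dir: str | Path
             ) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the full file bundle and its ground truth.

    Returns ``(paths, truth)`` where ``paths`` maps logical names
    (e.g. ``"counts"``, ``"peaks_ES"``) to the files written.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    transitions = config.transitions
    paths: dict[str, Path] = {}

    # ---- gene loci ----------------------------------------------------
    loci_per_chrom = config.chrom_length // LOCUS_SPAN
    genes: list[GeneAnnotation] = []
    tf_flags = np.zeros(config.n_genes, dtype=bool)
    tf_idx = rng.choice(config.n_genes, int(config.tf_fraction * config.n_genes),
                        replace=False)
    tf_flags[tf_idx] = True
    for gi in range(config.n_genes):
        chrom = f"chr{gi // loci_per_chrom + 1}"
        x = (gi % loci_per_chrom) * LOCUS_SPAN
        gid = f"G{gi:04d}"
        genes.append(GeneAnnotation(
            gene_id=gid, symbol=f"Sym{gi:04d}", tss=x,
            body=GenomicInterval(chrom, x, x + GENE_BODY_LEN, "+"),
            strand="+", is_tf=bool(tf_flags[gi]),
        ))
    paths["genes"] = out / "genes.tsv"
    io.write_gene_annotation(paths["genes"], genes)

    # ---- motif set and TF catalog ------------------------------------
    motifs = builtin_motifs()
    paths["pwms"] = out / "pwms.txt"
    io.write_pwms(paths["pwms"], motifs)
    tf_gene_ids = [genes[i].gene_id for i in sorted(tf_idx)]
    families = [fam for _, fam, _ in _BUILTIN_CONSENSI]
    catalog: dict[str, tuple[str, list[str]]] = {}
    members_of: dict[str, list[str]] = {}
    for fi, (motif_id, fam, _) in enumerate(_BUILTIN_CONSENSI):
        members = tf_gene_ids[2 * fi: 2 * fi + 2]
        members_of[fam] = members
        catalog[motif_id] = (fam, members)
    paths["tf_catalog"] = out / "tf_catalog.tsv"
    io.write_tf_catalog(paths["tf_catalog"], catalog)

    # ---- element layout and roles ------------------------------------
    # TF-catalog member genes have fixed expression profiles (set below),
    # so they must not host elements: a primed host gene's planted
    # low-then-up profile would otherwise be overwritten.
    member_ids = {gid for fam in families for gid in members_of[fam]}
    eligible = np.array([i for i, g in enumerate(genes)
                         if g.gene_id not in member_ids])
    n = config.n_elements
    host_gene_idx = np.sort(rng.choice(eligible, n, replace=False))
    elem_intervals: list[GenomicInterval] = []
    intragenic = rng.random(n) < config.intragenic_fraction
    for k, gi in enumerate(host_gene_idx):
        g = genes[gi]
        off = INTRAGENIC_OFFSET if intragenic[k] else INTERGENIC_OFFSET
        start = g.tss + off
        elem_intervals.append(GenomicInterval(g.body.chrom, start, start + ELEMENT_LEN))
    # host_gene_idx is sorted, so elements are already in (chrom, start)
    # order within <=9 chromosomes; ids match the merge step downstream
    elem_ids = [f"elem_{k + 1:05d}" for k in range(n)]
    element_gene = {elem_ids[k]: genes[host_gene_idx[k]].gene_id for k in range(n)}

    n_primed = config.n_primed_per_transition
    roles: list[tuple[str, str]] = []  # (role, transition label or "")
    for s1, s2 in transitions:
        roles += [(PRIMED, f"{s1}>{s2}")] * n_primed
    for s1, s2 in transitions:
        roles += [(ACTIVE, f"{s1}>{s2}")] * n_primed
    remaining = n - len(roles)
    if remaining < 0:
        raise ValueError("primed_fraction too high for the element count")
    n_each = remaining // 3
    roles += [(SILENT_GENE, "")] * n_each
    roles += [(NONPOSITIVE, "")] * n_each
    roles += [(SINGLE_STAGE, "")] * (remaining - 2 * n_each)
    order = rng.permutation(n)
    role_of = {elem_ids[order[i]]: roles[i] for i in range(n)}
    # assign a random transition to roleless gate-failure elements
    for eid in elem_ids:
        role, tr = role_of[eid]
        if role in (SILENT_GENE, SINGLE_STAGE, NONPOSITIVE) and not tr:
            s1, s2 = transitions[int(rng.integers(len(transitions)))]
            role_of[eid] = (role, f"{s1}>{s2}")

    # ---- open/positive profiles and true states ----------------------
    open_at: dict[str, dict[str, bool]] = {s: {} for s in stages}
    positive_at: dict[str, dict[str, bool]] = {s: {} for s in stages}
    states: dict[str, dict[str, str]] = {s: {} for s in stages}
    for eid in elem_ids:
        role, tr = role_of[eid]
        s1, s2 = tr.split(">")
        i1, i2 = stages.index(s1), stages.index(s2)
        opens = {s: False for s in stages}
        pos = {s: False for s in stages}
        if role in (PRIMED, ACTIVE, SILENT_GENE):
            opens[s1] = opens[s2] = True
            pos[s1] = pos[s2] = True
            for j, s in enumerate(stages):
                if j > i2 and rng.random() < config.persistence_prob:
                    opens[s] = pos[s] = True
                if j < i1 and rng.random() < 0.3:
                    opens[s] = pos[s] = True
        elif role == SINGLE_STAGE:
            opens[s1] = pos[s1] = True
        elif role == NONPOSITIVE:
            opens[s1] = True  # peak with no recovered fragments
        for s in stages:
            open_at[s][eid] = opens[s]
            positive_at[s][eid] = pos[s]
            if pos[s]:
                states[s][eid] = "High" if rng.random() < 0.5 else "Low"

    # ---- per-stage ATAC peaks (jittered copies of the element) -------
    peaks_per_stage: dict[str, dict[str, GenomicInterval]] = {}
    for s in stages:
        peaks: dict[str, GenomicInterval] = {}
        k = 0
        for eid, iv in zip(elem_ids, elem_intervals):
            if open_at[s][eid]:
                k += 1
                j1 = int(rng.integers(0, 51))
                j2 = int(rng.integers(0, 51))
                peaks[f"{s}_peak_{k:05d}"] = GenomicInterval(
                    iv.chrom, iv.start - j1, iv.end + j2)
        peaks_per_stage[s] = peaks
        paths[f"peaks_{s}"] = out / f"peaks_{s}.bed"
        names = sorted(peaks)
        io.write_bed(paths[f"peaks_{s}"], [peaks[p] for p in names], names=names)

    # ---- sorted fragment libraries, plasmid, negatives ---------------
    iv_of = dict(zip(elem_ids, elem_intervals))
    seen: dict[str, set] = {"high": set(), "low": set()}
    frags: dict[str, dict[str, list[GenomicInterval]]] = {
        s: {"high": [], "low": []} for s in stages}
    for s in stages:
        for eid in elem_ids:
            if not positive_at[s][eid]:
                continue
            iv = iv_of[eid]
            p_high = (config.high_fragment_prob if states[s][eid] == "High"
                      else 1.0 - config.high_fragment_prob)
            depth = config.fragment_depth
            if config.noiseless:
                n_high = int(round(p_high * depth))
            else:
                n_high = int(rng.binomial(depth, p_high))
            for fi in range(depth):
                lib = "high" if fi < n_high else "low"
                frag = _unique_fragment(rng, iv.chrom, iv.start - 100, iv.end + 100,
                                        seen[lib])
                frags[s][lib].append(frag)

    all_screen = [f for s in stages for lib in ("high", "low") for f in frags[s][lib]]
    n_artefact = 0 if config.noiseless else int(config.artefact_rate * len(all_screen))
    artefact_keys = set()
    if n_artefact:
        pick = rng.choice(len(all_screen), n_artefact, replace=False)
        artefact_keys = {all_screen[i].key for i in pick}
    plasmid = [f for f in all_screen if f.key not in artefact_keys]

    # background fragments: in plasmid and screen, but outside any peak
    bg_seen: set = set()
    background: list[GenomicInterval] = []
    for _ in range(0 if config.noiseless else config.n_background_fragments):
        gi = int(rng.integers(config.n_genes))
        g = genes[gi]
        frag = _unique_fragment(rng, g.body.chrom, g.tss + 14_000, g.tss + 18_000,
                                bg_seen)
        background.append(frag)
    plasmid = plasmid + background
    # distribute background into the sorted libraries round-robin
    for i, frag in enumerate(background):
        s = stages[i % len(stages)]
        frags[s]["high" if i % 2 == 0 else "low"].append(frag)

    # negative-control contamination: fragments present in both a screen
    # library and the negative-control library (removed by filter step 1)
    negatives: list[GenomicInterval] = []
    neg_seen: set = set()
    n_contam = (0 if config.noiseless
                else int(config.negative_contamination_rate * len(all_screen)))
    for i in range(n_contam):
        gi = int(rng.integers(config.n_genes))
        g = genes[gi]
        frag = _unique_fragment(rng, g.body.chrom, g.tss + 10_000, g.tss + 13_000,
                                neg_seen)
        negatives.append(frag)
        s = stages[i % len(stages)]
        frags[s]["high" if i % 2 == 0 else "low"].append(frag)
    # plus negative-only fragments
    for _ in range(0 if config.noiseless else 100):
        gi = int(rng.integers(config.n_genes))
        g = genes[gi]
        negatives.append(_unique_fragment(rng, g.body.chrom, g.tss + 10_000,
                                          g.tss + 13_000, neg_seen))

    for s in stages:
        for lib, label in (("high", "sorted_high"), ("low", "sorted_low")):
            key = f"frags_{label}_{s}"
            paths[key] = out / f"{key}.bed"
            io.write_bed(paths[key], frags[s][lib])
    paths["plasmid"] = out / "plasmid.bed"
    io.write_bed(paths["plasmid"], plasmid)
    paths["negatives"] = out / "negatives.bed"
    io.write_bed(paths["negatives"], negatives)

    # ---- expression counts -------------------------------------------
    # Planted genes (element hosts, TF members) carry absolute CPM
    # targets; the remaining background genes are rescaled per stage so
    # each column sums to exactly 1e6, i.e. realized CPM = target for
    # every planted gene (up to count noise).
    target = np.empty((config.n_genes, len(stages)))
    base = 2.0 ** rng.normal(config.baseline_log2_cpm, config.baseline_log2_cpm_sd,
                             config.n_genes)
    target[:] = base[:, None]
    planted_mask = np.zeros(config.n_genes, dtype=bool)
    lo, hi = config.primed_low_cpm
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    primed_pairs: dict[str, list[tuple[str, str]]] = {
        f"{s1}>{s2}": [] for s1, s2 in transitions}
    for eid in elem_ids:
        role, tr = role_of[eid]
        gid = element_gene[eid]
        gi = gene_index[gid]
        s1, s2 = tr.split(">")
        i2 = stages.index(s2)
        if role == PRIMED:
            low = rng.uniform(lo, hi)
            target[gi, :i2] = low
            target[gi, i2:] = low * config.primed_fold_change
            primed_pairs[tr].append((eid, gid))
            planted_mask[gi] = True
        elif role == ACTIVE:
            target[gi, :] = rng.uniform(50, 300)  # expressed throughout
            planted_mask[gi] = True
        elif role == SILENT_GENE:
            target[gi, :] = rng.uniform(1, 4)  # never expressed, no DE
            planted_mask[gi] = True
    # TF family member expression
    expressed_tfs: dict[str, set[str]] = {s: set() for s in stages}
    for fam in families:
        late = fam in _LATE_FAMILIES
        for gid in members_of[fam]:
            gi = gene_index[gid]
            if late:
                target[gi, :2] = rng.uniform(1, 4)
                target[gi, 2:] = rng.uniform(50, 150)
            else:
                target[gi, :] = rng.uniform(50, 200)
            planted_mask[gi] = True
    # rescale background genes so each stage column sums to 1e6; planted
    # genes keep their absolute CPM targets
    planted_sum = target[planted_mask].sum(axis=0)
    if (planted_sum >= 0.8e6).any():
        raise ValueError("planted expression exceeds the CPM budget")
    bg_sum = target[~planted_mask].sum(axis=0)
    target[~planted_mask] *= (1e6 - planted_sum) / bg_sum
    for si, s in enumerate(stages):
        for gid in tf_gene_ids:
            if target[gene_index[gid], si] >= 9.0:
                expressed_tfs[s].add(gid)

    cols, mus = [], []
    for si, s in enumerate(stages):
        for r in range(1, config.replicates + 1):
            cols.append(f"{s}_rep{r}")
            mus.append(target[:, si] * (config.library_size / 1e6))
    counts = np.column_stack([
        _nb_draw(rng, mu, config.dispersion, config.noiseless) for mu in mus])
    counts_df = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=cols)
    paths["counts"] = out / "counts.tsv"
    io.write_expression(paths["counts"], ExpressionTable(counts_df))

    # ---- CHi-C links --------------------------------------------------
    links: list[InteractionLink] = []
    chic = rng.random(n) < config.chic_fraction
    for k, eid in enumerate(elem_ids):
        if chic[k]:
            iv = iv_of[eid]
            links.append(InteractionLink(
                element_gene[eid],
                GenomicInterval(iv.chrom, iv.start - 200, iv.end + 200),
                float(np.round(rng.uniform(1, 10), 3)),
            ))
    paths["chic_links"] = out / "chic_links.tsv"
    io.write_links(paths["chic_links"], links)

    # ---- element sequences with planted motifs -----------------------
    consensus_of = {mid: cons for mid, _, cons in _BUILTIN_CONSENSI}
    motif_by_family = {fam: mid for mid, fam, _ in _BUILTIN_CONSENSI}
    motif_content: dict[str, list[str]] = {}
    seqs: dict[str, str] = {}
    for eid in elem_ids:
        seq = list("".join(rng.choice(list("ACGT"), ELEMENT_LEN)))
        planted: list[str] = []
        role, _ = role_of[eid]
        if role in (PRIMED, ACTIVE):
            n_mot = int(rng.integers(1, 4))
            fams = [str(rng.choice(_EARLY_FAMILIES))]
            fams += [str(rng.choice(families)) for _ in range(n_mot - 1)]
            slot = 20
            for fam in fams:
                mid = motif_by_family[fam]
                cons = consensus_of[mid]
                seq[slot:slot + len(cons)] = list(cons)
                if mid not in planted:
                    planted.append(mid)
                slot += len(cons) + 30
        motif_content[eid] = planted
        seqs[eid] = "".join(seq)
    paths["elements_fasta"] = out / "elements.fa"
    io.write_fasta(paths["elements_fasta"], seqs)

    # ---- ChIP-like feature peak sets ---------------------------------
    feature_names = ["H3K27ac", "H3K4me1", "H3K27me3", "RUNX1_chip",
                     "FLI1_chip", "TEAD4_chip"]
    for fname in feature_names:
        base_rate = rng.uniform(0.2, 0.8)
        covered = []
        for k, eid in enumerate(elem_ids):
            role, _ = role_of[eid]
            rate = base_rate + (0.05 if role == PRIMED else 0.0)
            if rng.random() < rate:
                iv = iv_of[eid]
                covered.append(GenomicInterval(iv.chrom, iv.start - 20, iv.end + 20))
        paths[f"feature_{fname}"] = out / f"feature_{fname}.bed"
        io.write_bed(paths[f"feature_{fname}"], covered)

    # ---- eRNA tag counts (element x stage) ---------------------------
    erna_mu = np.full((n, len(stages)), 2.0)
    for k, eid in enumerate(elem_ids):
        role, tr = role_of[eid]
        if role in (PRIMED, ACTIVE):
            s1, s2 = tr.split(">")
            i2 = stages.index(s2)
            if role == PRIMED:
                erna_mu[k, i2:] = 50.0  # eRNA appears with gene activation
            else:
                erna_mu[k, :] = 50.0
    erna_counts = _nb_draw(rng, erna_mu, config.dispersion, config.noiseless)
    erna_df = pd.DataFrame(erna_counts, index=elem_ids, columns=stages)
    paths["erna_counts"] = out / "erna_counts.tsv"
    erna_df.to_csv(paths["erna_counts"], sep="\t", index_label="element_id")

    # ---- VEGF condition peaks and expression -------------------------
    s1v, s2v = transitions[-1]
    last_tr = f"{s1v}>{s2v}"
    last_primed = [eid for eid, _ in primed_pairs[last_tr]]
    n_resp = int(round(config.vegf_responsive_fraction * len(last_primed)))
    responsive = sorted(rng.choice(last_primed, n_resp, replace=False).tolist())
    active_last = sorted(eid for eid in elem_ids
                         if role_of[eid] == (ACTIVE, last_tr))
    opposite = active_last[:4]
    for s in (s1v, s2v):
        minus, allc = [], []
        for eid in elem_ids:
            if not open_at[s][eid]:
                continue
            iv = iv_of[eid]
            piv = GenomicInterval(iv.chrom, iv.start - 30, iv.end + 30)
            if eid in responsive:
                minus.append(piv)
            elif eid in opposite:
                allc.append(piv)
            else:
                minus.append(piv)
                allc.append(piv)
        paths[f"vegf_minus_{s}"] = out / f"vegf_minusVEGF_{s}.bed"
        io.write_bed(paths[f"vegf_minus_{s}"], minus)
        paths[f"vegf_all_{s}"] = out / f"vegf_all_cytokines_{s}.bed"
        io.write_bed(paths[f"vegf_all_{s}"], allc)

    resp_genes = sorted({element_gene[eid] for eid in responsive})
    reps = config.condition_replicates
    rows_minus, rows_plus = [], []
    report_genes = sorted({element_gene[eid] for eid, _ in primed_pairs[last_tr]})
    for gid in report_genes:
        base_expr = float(target[gene_index[gid], stages.index(s1v)])
        if gid in resp_genes:
            fold = rng.uniform(2, 6)
        else:
            fold = 1.0
        noise = 0.0 if config.noiseless else 0.1
        rows_plus.append(base_expr * np.maximum(
            1 + noise * rng.standard_normal(reps), 0.1))
        rows_minus.append(base_expr * fold * np.maximum(
            1 + noise * rng.standard_normal(reps), 0.1))
    rep_cols = [f"rep{r}" for r in range(1, reps + 1)]
    pd.DataFrame(np.round(rows_minus, 4), index=report_genes, columns=rep_cols
                 ).to_csv(out / "vegf_expr_minus.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(np.round(rows_plus, 4), index=report_genes, columns=rep_cols
                 ).to_csv(out / "vegf_expr_plus.tsv", sep="\t", index_label="gene_id")
    paths["vegf_expr_minus"] = out / "vegf_expr_minus.tsv"
    paths["vegf_expr_plus"] = out / "vegf_expr_plus.tsv"

    # ---- ground truth -------------------------------------------------
    truth = GroundTruth(
        primed_pairs=primed_pairs,
        states={s: dict(sorted(states[s].items())) for s in stages},
        positive={s: sorted(e for e in elem_ids if positive_at[s][e])
                  for s in stages},
        motif_content=motif_content,
        vegf_responsive=responsive,
        vegf_opposite=opposite,
        expressed_tfs={s: sorted(expressed_tfs[s]) for s in stages},
        element_gene=element_gene,
        element_role={e: role_of[e][0] for e in elem_ids},
        element_transition={e: role_of[e][1] for e in elem_ids},
    )
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    return paths, truth


# ---------------------------------------------------------------------------
# Evaluation against planted truth


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float | None  # None when nothing was called
    recall: float | None


def evaluate(predicted, truth, universe: Sequence[str] | None = None) -> EvalResult:
    """Binary confusion metrics of a call set against the planted truth.

    ``predicted`` and ``truth`` are collections of ids (or id tuples).
    With ``universe`` given, any id outside it is an error (guards
    against comparing mismatched id spaces). Precision is ``None`` when
    nothing was called; recall is ``None`` when the truth set is empty.
    """
    pred = set(predicted)
    true = set(truth)
    if universe is not None:
        uni = set(universe)
        stray = (pred | true) - uni
        if stray:
            raise ValueError(f"ids outside the shared universe: {sorted(stray)[:5]}")
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    precision = tp / (tp + fp) if pred else None
    recall = tp / (tp + fn) if true else None
    return EvalResult(tp, fp, fn, precision, recall)
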