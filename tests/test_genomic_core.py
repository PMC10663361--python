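"""Interval algebra: overlap semantics, TSS distances, nearest-gene."""

import numpy as np
import pytest

from primescan.genomic_core import (
    GeneAnnotation,
    GenomicInterval,
    UnassignableError,
    distance_to_nearest_tss,
    find_overlaps,
    nearest_gene,
    overlaps,
)

from conftest import make_genes, random_intervals


def bases(iv):
    return set(range(iv.start, iv.end)) if True else set()


class TestGenomicInterval:
    @pytest.mark.parametrize("chrom,start,end", [
        ("", 0, 10), ("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 20, 10),
    ])
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_half_open_length(self):
        assert len(GenomicInterval("chr1", 100, 250)) == 150


class TestOverlaps:
    def test_shared_bases(self):
        a = GenomicInterval("chr1", 100, 200)
        assert overlaps(a, GenomicInterval("chr1", 150, 250))

    def test_abutting_intervals_do_not_overlap(self):
        # half-open: [100,200) and [200,300) share no base
        a = GenomicInterval("chr1", 100, 200)
        assert not overlaps(a, GenomicInterval("chr1", 200, 300))

    def test_different_chromosomes(self):
        a = GenomicInterval("chr1", 100, 200)
        assert not overlaps(a, GenomicInterval("chr2", 100, 200))

    def test_agrees_with_base_set_oracle(self, rng):
        # 200 random pairs against per-base set intersection
        ivs = random_intervals(rng, 400)
        for a, b in zip(ivs[:200], ivs[200:]):
            expected = (a.chrom == b.chrom
                        and bool(set(range(a.start, a.end))
                                 & set(range(b.start, b.end))))
            assert overlaps(a, b) == expected

    def test_symmetric_and_reflexive(self, rng):
        ivs = random_intervals(rng, 60)
        for a, b in zip(ivs[:30], ivs[30:]):
            assert overlaps(a, b) == overlaps(b, a)
        for a in ivs:
            assert overlaps(a, a)


class TestFindOverlaps:
    def test_empty_queries(self):
        assert find_overlaps([], random_intervals(np.random.default_rng(0), 5)) == []

    def test_one_query_two_subjects(self):
        q = [GenomicInterval("chr1", 100, 300)]
        s = [GenomicInterval("chr1", 50, 150), GenomicInterval("chr1", 250, 400),
             GenomicInterval("chr1", 500, 600)]
        assert find_overlaps(q, s) == [(0, 0), (0, 1)]

    def test_matches_all_pairs_brute_force(self, rng):
        queries = random_intervals(rng, 300)
        subjects = random_intervals(rng, 300)
        expected = sorted(
            (i, j)
            for i, q in enumerate(queries)
            for j, s in enumerate(subjects)
            if overlaps(q, s)
        )
        assert find_overlaps(queries, subjects) == expected

    def test_content_invariant_under_shuffle(self, rng):
        queries = random_intervals(rng, 50)
        subjects = random_intervals(rng, 50)
        ref = find_overlaps(queries, subjects)
        perm = rng.permutation(len(subjects))
        shuffled = [subjects[k] for k in perm]
        remapped = sorted((i, int(perm[j])) for i, j in find_overlaps(queries, shuffled))
        assert remapped == ref


class TestTSSDistance:
    def test_tss_inside_peak_gives_zero(self):
        genes = make_genes([1200])
        peak = GenomicInterval("chr1", 1000, 1500)
        assert distance_to_nearest_tss(peak, genes) == (0, "G000")

    def test_distal_boundary_at_1500bp(self):
        # nearest TSS 1601 bp from the peak edge: distal under the
        # >1.5 kb rule
        genes = make_genes([3100])
        peak = GenomicInterval("chr1", 1000, 1500)
        dist, gid = distance_to_nearest_tss(peak, genes)
        assert dist == min(abs(3100 - 1000), abs(3100 - 1499)) == 1601
        assert dist > 1500

    def test_matches_exhaustive_scan(self, rng):
        positions = sorted(rng.choice(50_000, 50, replace=False))
        genes = make_genes(positions)
        for _ in range(100):
            start = int(rng.integers(0, 49_000))
            peak = GenomicInterval("chr1", start, start + int(rng.integers(1, 800)))
            expected = min(
                (0 if peak.start <= g.tss < peak.end
                 else min(abs(g.tss - peak.start), abs(g.tss - (peak.end - 1))),
                 g.gene_id)
                for g in genes
            )
            assert distance_to_nearest_tss(peak, genes) == expected

    def test_invariant_to_annotation_order_and_strand(self, rng):
        genes = make_genes([500, 9000, 22_000])
        flipped = [GeneAnnotation(g.gene_id, g.symbol, g.tss, g.body, "-", g.is_tf)
                   for g in genes]
        peak = GenomicInterval("chr1", 4000, 4200)
        ref = distance_to_nearest_tss(peak, genes)
        assert distance_to_nearest_tss(peak, genes[::-1]) == ref
        assert distance_to_nearest_tss(peak, flipped) == ref

    def test_no_gene_on_chromosome_is_unassignable(self):
        with pytest.raises(UnassignableError):
            distance_to_nearest_tss(GenomicInterval("chrX", 0, 100), make_genes([10]))


class TestNearestGene:
    def test_tie_breaks_to_smallest_gene_id(self):
        # two TSS equidistant from the peak edges
        genes = make_genes([1000, 3099])  # peak [2000,2100): d=1000 both
        peak = GenomicInterval("chr1", 2000, 2100)
        d0 = distance_to_nearest_tss(peak, [genes[0]])[0]
        d1 = distance_to_nearest_tss(peak, [genes[1]])[0]
        assert d0 == d1
        assert nearest_gene(peak, genes) == "G000"
        assert nearest_gene(peak, genes[::-1]) == "G000"

    def test_single_gene(self):
        genes = make_genes([40_000])
        assert nearest_gene(GenomicInterval("chr1", 0, 10), genes) == "G000"
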