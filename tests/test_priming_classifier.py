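"""Priming gates, dynamics classes, persistence and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from primescan.expression_stats import DEResult, cpm
from primescan.genomic_core import GenomicInterval, overlaps
from primescan.io_formats import InteractionLink
from primescan.priming_classifier import (
    StageOrder,
    aggregate_element_calls,
    classify_primed,
    dynamics_class,
    link_peak_to_gene,
    median_expression_zscore,
    merge_elements,
    multiplicity_per_gene,
    persistence,
)
from primescan.screen_activity import EnhancerCall

from conftest import make_expression, make_genes, random_intervals


def call(eid, stage, state):
    if state == "NotPositive":
        return EnhancerCall(eid, stage, False, 0, 0, 0.0, 0.0, state)
    nh, nl = (3, 1) if state == "High" else (1, 3)
    return EnhancerCall(eid, stage, True, nh, nl, float(nh), float(nl), state)


class TestLinkPeakToGene:
    def test_chic_overlap_wins(self):
        genes = make_genes([50_000])
        links = [InteractionLink("GX", GenomicInterval("chr1", 900, 1100), 5.0)]
        peak = GenomicInterval("chr1", 1000, 1200)
        assert link_peak_to_gene(peak, links, genes) == ("GX", "chic")

    def test_no_interaction_falls_back_to_nearest(self):
        genes = make_genes([50_000])
        peak = GenomicInterval("chr1", 1000, 1200)
        assert link_peak_to_gene(peak, [], genes) == ("G000", "nearest")

    def test_highest_score_interaction_selected(self):
        peak = GenomicInterval("chr1", 1000, 1200)
        links = [InteractionLink("GA", GenomicInterval("chr1", 900, 1100), 2.0),
                 InteractionLink("GB", GenomicInterval("chr1", 1100, 1300), 7.0)]
        assert link_peak_to_gene(peak, links, make_genes([0]))[0] == "GB"

    def test_matches_two_pass_brute_force(self, rng):
        genes = make_genes(sorted(rng.choice(40_000, 30, replace=False)))
        links = [InteractionLink(f"G{int(rng.integers(30)):03d}", iv,
                                 float(rng.random()))
                 for iv in random_intervals(rng, 40, n_chroms=1, span=40_000)]
        for _ in range(60):
            s = int(rng.integers(0, 39_000))
            peak = GenomicInterval("chr1", s, s + int(rng.integers(50, 600)))
            hits = [l for l in links if overlaps(peak, l.other_end)]
            if hits:
                expect = (min(hits, key=lambda l: (-l.score, l.bait_gene)).bait_gene,
                          "chic")
            else:
                expect = (min(
                    ((min(abs(g.tss - peak.start), abs(g.tss - (peak.end - 1)))
                      if not (peak.start <= g.tss < peak.end) else 0, g.gene_id)
                     for g in genes))[1], "nearest")
            assert link_peak_to_gene(peak, links, genes) == expect


class TestDynamics:
    @pytest.mark.parametrize("s1,s2,label", [
        ("High", "High", "High>High"), ("Low", "Low", "Low>Low"),
        ("Low", "High", "Low>High"), ("High", "Low", "High>Low")])
    def test_all_four_combinations(self, s1, s2, label):
        assert dynamics_class(s1, s2) == label

    def test_not_positive_rejected(self):
        with pytest.raises(ValueError):
            dynamics_class("NotPositive", "High")


class TestMergeElements:
    def test_overlapping_stage_peaks_form_one_element(self):
        peaks = {"ES": {"a": GenomicInterval("chr1", 100, 300)},
                 "HB": {"b": GenomicInterval("chr1", 250, 500)}}
        elements, membership = merge_elements(peaks)
        (eid,) = elements
        assert elements[eid] == GenomicInterval("chr1", 100, 500)
        assert membership[eid] == {"ES": ["a"], "HB": ["b"]}

    def test_abutting_peaks_stay_separate(self):
        peaks = {"ES": {"a": GenomicInterval("chr1", 100, 300),
                        "b": GenomicInterval("chr1", 300, 500)}}
        elements, _ = merge_elements(peaks)
        assert len(elements) == 2


class _Scenario:
    """Two genes, two elements; one a textbook primed element, the other
    failing the not-expressed gate."""

    def __init__(self):
        self.genes = make_genes([0, 20_000])
        self.elements = {
            "e1": GenomicInterval("chr1", 8000, 8500),   # distal to G000
            "e2": GenomicInterval("chr1", 28_000, 28_500),  # distal to G001
        }
        self.calls = {
            s: {e: call(e, s, st) for e, st in zip(
                ("e1", "e2"), states)}
            for s, states in {"ES": ("Low", "High"), "HB": ("High", "High")}.items()
        }
        # G000 silent at ES then induced; G001 already expressed at ES
        self.expr = cpm(make_expression(
            {"G000": [2, 3, 40, 45], "G001": [300, 310, 305, 300],
             "pad": [1_000_000] * 4}, ["ES", "HB"], 2))
        self.de = [
            DEResult("G000", ("ES", "HB"), 3.8, 1e-6, 1e-4, "external"),
            DEResult("G001", ("ES", "HB"), 0.0, 0.9, 0.95, "external"),
        ]

    def classify(self, **kw):
        return classify_primed(("ES", "HB"), self.calls, self.elements,
                               self.genes, [], self.expr, self.de, **kw)


class TestClassifyPrimed:
    def test_textbook_primed_element_recovered(self):
        (rec,) = _Scenario().classify()
        assert rec.peak_id == "e1" and rec.gene_id == "G000"
        assert rec.link_method == "nearest"
        assert rec.dynamics == "Low>High"

    def test_expressed_gene_blocks_priming(self):
        recs = _Scenario().classify()
        assert all(r.gene_id != "G001" for r in recs)

    def test_positive_at_one_stage_only_is_not_primed(self):
        sc = _Scenario()
        sc.calls["HB"]["e1"] = call("e1", "HB", "NotPositive")
        assert sc.classify() == []

    def test_proximal_element_excluded(self):
        sc = _Scenario()
        sc.elements["e1"] = GenomicInterval("chr1", 900, 1400)  # 900 bp from TSS
        assert sc.classify() == []

    def test_missing_de_table_is_error(self):
        sc = _Scenario()
        sc.de = [DEResult("G000", ("HB", "HE"), 2.0, 0.01, 0.02, "external")]
        with pytest.raises(ValueError, match="ES->HB"):
            sc.classify()

    def test_raising_distal_cutoff_never_grows_the_set(self):
        sc = _Scenario()
        base = {r.peak_id for r in sc.classify(distal_min_bp=1500)}
        for cutoff in (3000, 8000, 30_000):
            assert {r.peak_id for r in sc.classify(distal_min_bp=cutoff)} <= base

    def test_records_repass_all_gates(self):
        # self-audit: every emitted record satisfies the four gates when
        # re-checked independently
        from primescan.expression_stats import is_expressed
        from primescan.genomic_core import distance_to_nearest_tss
        sc = _Scenario()
        de = {r.gene_id: r for r in sc.de}
        for rec in sc.classify():
            assert distance_to_nearest_tss(sc.elements[rec.peak_id],
                                           sc.genes)[0] > 1500
            assert sc.calls["ES"][rec.peak_id].positive
            assert sc.calls["HB"][rec.peak_id].positive
            assert not is_expressed(rec.gene_id, "ES", sc.expr)
            assert de[rec.gene_id].log2fc >= 1 and de[rec.gene_id].padj < 0.05


class TestPersistence:
    def _calls(self, table):
        # table: element -> {stage: positive?}
        stages = ("ES", "HB", "HE", "HP")
        return {s: {e: call(e, s, "High" if table[e].get(s) else "NotPositive")
                    for e in table} for s in stages}

    def _primed(self, eids):
        from primescan.priming_classifier import PrimedRecord
        return [PrimedRecord(e, ("ES", "HB"), "G000", "nearest",
                             "High", "High", "High>High") for e in eids]

    def test_all_positive_everywhere_is_100(self):
        calls = self._calls({"e1": {"ES": 1, "HB": 1, "HE": 1, "HP": 1}})
        out = persistence(self._primed(["e1"]), calls, StageOrder())
        assert out == {"HB": 100.0, "HE": 100.0, "HP": 100.0}

    def test_half_positive_at_final_stage(self):
        calls = self._calls({
            "e1": {"ES": 1, "HB": 1, "HE": 1, "HP": 1},
            "e2": {"ES": 1, "HB": 1, "HE": 0, "HP": 0}})
        out = persistence(self._primed(["e1", "e2"]), calls, StageOrder())
        assert out["HP"] == 50.0 and out["HB"] == 100.0

    def test_empty_primed_set_gives_empty_result(self):
        assert persistence([], {}, StageOrder()) == {}


class TestExpressionZscores:
    def test_monotone_gene_gives_increasing_median(self):
        t = cpm(make_expression(
            {"g1": [10, 10, 100, 100, 1000, 1000, 10_000, 10_000],
             "pad": [1e6] * 8}, ["ES", "HB", "HE", "HP"], 2))
        z = median_expression_zscore(["g1"], t, StageOrder())
        assert (np.diff(z.values) > 0).all()

    def test_constant_gene_contributes_zeros(self):
        t = cpm(make_expression(
            {"g1": [50] * 8, "pad": [1e6] * 8}, ["ES", "HB", "HE", "HP"], 2))
        z = median_expression_zscore(["g1"], t, StageOrder())
        assert np.allclose(z.values, 0.0)

    def test_per_gene_standardisation(self, rng):
        data = {f"g{i}": rng.integers(1, 5000, 8).tolist() for i in range(50)}
        data["pad"] = [1e6] * 8
        t = cpm(make_expression(data, ["ES", "HB", "HE", "HP"], 2))
        from primescan.priming_classifier import _stage_log_cpm
        prof = _stage_log_cpm(t, ["ES", "HB", "HE", "HP"])
        prof = prof.loc[[f"g{i}" for i in range(50)]]
        z = prof.sub(prof.mean(axis=1), axis=0).div(prof.std(axis=1, ddof=0), axis=0)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)


class TestMultiplicity:
    def test_counts_and_conservation(self):
        from primescan.priming_classifier import PrimedRecord
        recs = [PrimedRecord(f"e{i}", ("ES", "HB"), g, "nearest", "High",
                             "High", "High>High")
                for i, g in enumerate(["GA", "GA", "GA", "GB"])]
        counts = multiplicity_per_gene(recs)
        assert counts["GA"] == 3 and counts["GB"] == 1
        assert counts.sum() == len(recs)
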