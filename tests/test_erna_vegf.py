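"""eRNA Z-score summaries and VEGF-responsiveness classification."""

import numpy as np
import pandas as pd
import pytest

from primescan.erna_vegf import (
    classify_intergenic,
    classify_vegf_responsive,
    erna_zscores,
    vegf_gene_report,
)
from primescan.genomic_core import GenomicInterval

from conftest import make_genes, random_intervals


class TestIntergenic:
    def test_element_inside_gene_body_is_intragenic(self):
        genes = make_genes([1000])  # body [1000, 2000)
        elements = {"e1": GenomicInterval("chr1", 1500, 1600),
                    "e2": GenomicInterval("chr1", 8000, 8100),
                    "e3": GenomicInterval("chrZ", 0, 100)}
        inter, intra = classify_intergenic(elements, genes)
        assert intra == ["e1"]
        assert inter == ["e2", "e3"]  # no genes on chrZ -> intergenic

    def test_partition_is_complete(self, rng):
        genes = make_genes([0, 5000, 9000])
        elements = {f"e{i}": iv
                    for i, iv in enumerate(random_intervals(rng, 30, span=12_000))}
        inter, intra = classify_intergenic(elements, genes)
        assert sorted(inter + intra) == sorted(elements)


class TestErnaZscores:
    def test_activation_stage_has_maximal_z(self):
        counts = pd.DataFrame({"ES": [2], "HB": [2], "HE": [60], "HP": [70]},
                              index=["e1"])
        z = erna_zscores(counts, ["ES", "HB", "HE", "HP"],
                         library_sizes={s: 1000.0 for s in "ES HB HE HP".split()})
        assert z.idxmax() == "HP" and z["HE"] > z["ES"]

    def test_all_zero_elements_contribute_zero(self):
        counts = pd.DataFrame({"ES": [0], "HB": [0]}, index=["e1"])
        z = erna_zscores(counts, ["ES", "HB"],
                         library_sizes={"ES": 100.0, "HB": 100.0})
        assert np.allclose(z.values, 0.0)

    def test_per_element_standardisation(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (40, 4)),
                              columns=["ES", "HB", "HE", "HP"],
                              index=[f"e{i}" for i in range(40)])
        lib = {s: 10_000.0 for s in counts.columns}
        logv = np.log2(1e6 * counts / pd.Series(lib) + 0.5)
        sd = logv.std(axis=1, ddof=0)
        z = logv.sub(logv.mean(axis=1), axis=0).div(sd.where(sd > 0, 1), axis=0)
        z[sd == 0] = 0
        nonconst = sd > 0
        assert np.allclose(z[nonconst].mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z[nonconst].std(axis=1, ddof=0), 1, atol=1e-9)
        assert np.allclose(
            erna_zscores(counts, list(counts.columns), lib).values,
            z.median(axis=0).values)

    def test_invariant_to_uniform_library_scaling(self, rng):
        counts = pd.DataFrame(rng.integers(0, 300, (10, 3)),
                              columns=["A", "B", "C"],
                              index=[f"e{i}" for i in range(10)])
        z1 = erna_zscores(counts, ["A", "B", "C"],
                          {"A": 1000.0, "B": 1000.0, "C": 1000.0})
        z2 = erna_zscores(counts, ["A", "B", "C"],
                          {"A": 7000.0, "B": 7000.0, "C": 7000.0})
        # the +0.5 pseudo-CPM makes the invariance approximate at finite
        # counts; exact only in the infinite-depth limit
        assert np.allclose(z1.values, z2.values, atol=1e-3)

    def test_missing_stage_is_error(self):
        counts = pd.DataFrame({"A": [1]}, index=["e1"])
        with pytest.raises(ValueError, match="missing stage"):
            erna_zscores(counts, ["A", "B"])


class TestVegfResponsive:
    def _elements(self):
        return {"open_minus_only": GenomicInterval("chr1", 100, 600),
                "open_both": GenomicInterval("chr1", 5000, 5500),
                "open_plus_only": GenomicInterval("chr1", 9000, 9500),
                "closed": GenomicInterval("chr1", 14_000, 14_500)}

    def _peaks(self):
        minus = [GenomicInterval("chr1", 150, 550),
                 GenomicInterval("chr1", 5100, 5400)]
        allc = [GenomicInterval("chr1", 5100, 5400),
                GenomicInterval("chr1", 9100, 9400)]
        return minus, allc

    def test_direction_absence_of_vegf_opens(self):
        minus, allc = self._peaks()
        responsive, opposite = classify_vegf_responsive(self._elements(), minus, allc)
        assert responsive == ["open_minus_only"]
        assert opposite == ["open_plus_only"]

    def test_open_in_both_conditions_is_not_responsive(self):
        minus, allc = self._peaks()
        responsive, _ = classify_vegf_responsive(self._elements(), minus, allc)
        assert "open_both" not in responsive

    def test_anti_monotone_in_all_cytokines_peaks(self, rng):
        elements = {f"e{i}": iv
                    for i, iv in enumerate(random_intervals(rng, 30, span=4000))}
        minus = random_intervals(rng, 25, span=4000)
        allc = random_intervals(rng, 10, span=4000)
        base, _ = classify_vegf_responsive(elements, minus, allc)
        more, _ = classify_vegf_responsive(elements, minus,
                                           allc + random_intervals(rng, 15, span=4000))
        assert set(more) <= set(base)

    def test_matches_two_overlap_oracle(self, rng):
        from primescan.genomic_core import overlaps
        elements = {f"e{i}": iv
                    for i, iv in enumerate(random_intervals(rng, 40, span=4000))}
        minus = random_intervals(rng, 20, span=4000)
        allc = random_intervals(rng, 20, span=4000)
        responsive, opposite = classify_vegf_responsive(elements, minus, allc)
        for e, iv in elements.items():
            in_m = any(overlaps(iv, p) for p in minus)
            in_a = any(overlaps(iv, p) for p in allc)
            assert (e in responsive) == (in_m and not in_a)
            assert (e in opposite) == (in_a and not in_m)


class TestVegfGeneReport:
    def _tables(self):
        minus = pd.DataFrame({"rep1": [10.0, 40.0], "rep2": [10.0, 44.0]},
                             index=["same", "up"])
        plus = pd.DataFrame({"rep1": [10.0, 20.0], "rep2": [10.0, 22.0]},
                            index=["same", "up"])
        return minus, plus

    def test_identical_expression_gives_unit_fold_and_p_one(self):
        minus, plus = self._tables()
        rep = vegf_gene_report(["same"], minus, plus)
        assert rep.loc["same", "fold_change"] == pytest.approx(1.0)
        assert rep.loc["same", "p_bonferroni"] == 1.0

    def test_doubled_gene_has_fold_change_two(self):
        minus, plus = self._tables()
        rep = vegf_gene_report(["same", "up"], minus, plus)
        assert rep.loc["up", "fold_change"] == pytest.approx(2.0)

    def test_rows_are_subset_of_requested_genes(self):
        minus, plus = self._tables()
        rep = vegf_gene_report(["same", "up", "missing"], minus, plus)
        assert set(rep.index) <= {"same", "up"}

    def test_bonferroni_uses_supplied_family_size(self):
        minus, plus = self._tables()
        rep = vegf_gene_report(["up"], minus, plus, m=34)
        assert rep.loc["up", "p_bonferroni"] == pytest.approx(
            min(1.0, rep.loc["up", "pvalue"] * 34))
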