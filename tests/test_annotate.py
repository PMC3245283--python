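"""Feature categories, gene association geometry and CpG o/e."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methcapdmr.annotate as ann
from methcapdmr.core import FeatureCategory, GeneModel, GenomicInterval

from oracles import naive_cpg_counts


def _gene(gene_id="G1", chrom="chr1", strand="+", span=(20_000, 30_000),
          exons=()):
    s = GenomicInterval(chrom, *span, strand)
    ex = [GenomicInterval(chrom, a, b, strand) for a, b in exons]
    return GeneModel(gene_id, chrom, strand, s, ex)


class TestAssignFeature:
    def test_upstream_window_is_promoter(self):
        g = _gene(exons=[(20_000, 21_000)])
        dmr = GenomicInterval("chr1", 17_500, 18_000)  # 2 kb upstream of TSS
        assert ann.assign_feature(dmr, [g], []) is FeatureCategory.PROMOTER

    def test_exon_beats_repeat(self):
        g = _gene(exons=[(20_000, 21_000)])
        repeat = GenomicInterval("chr1", 20_400, 20_900)
        dmr = GenomicInterval("chr1", 20_500, 20_800)
        assert ann.assign_feature(dmr, [g], [repeat]) is FeatureCategory.EXON

    def test_inside_gene_without_exon_is_intron(self):
        g = _gene(exons=[(20_000, 21_000), (29_000, 30_000)])
        dmr = GenomicInterval("chr1", 24_000, 24_500)
        assert ann.assign_feature(dmr, [g], []) is FeatureCategory.INTRON

    def test_no_overlap_is_intergenic(self):
        g = _gene()
        dmr = GenomicInterval("chr1", 50_000, 50_500)
        assert ann.assign_feature(dmr, [g], []) is FeatureCategory.INTERGENIC

    def test_repeat_without_gene_context(self):
        repeat = GenomicInterval("chr1", 50_000, 50_600)
        dmr = GenomicInterval("chr1", 50_100, 50_400)
        assert ann.assign_feature(dmr, [], [repeat]) is FeatureCategory.REPEAT

    def test_promoter_is_strand_aware(self):
        minus = _gene(strand="-")
        # 2 kb PAST span end = upstream of the '-' TSS at 29_999
        dmr = GenomicInterval("chr1", 31_500, 32_000)
        assert ann.assign_feature(dmr, [minus], []) is FeatureCategory.PROMOTER
        # the same window is NOT promoter for a '+' gene
        plus = _gene(strand="+")
        assert ann.assign_feature(dmr, [plus], []) is FeatureCategory.INTERGENIC


class TestAssociateGenes:
    def test_dmr_containing_tss_is_overlap_start(self):
        g = _gene()
        dmr = GenomicInterval("chr1", 19_800, 20_300)
        (assoc,) = ann.associate_genes(dmr, [g])
        assert assoc.relation == "overlapStart"
        assert assoc.distance_to_tss == 0

    def test_upstream_within_flank(self):
        g = _gene()
        dmr = GenomicInterval("chr1", 16_000, 16_500)
        (assoc,) = ann.associate_genes(dmr, [g])
        assert assoc.relation == "upstream"
        assert assoc.distance_to_tss < 0

    def test_downstream_within_flank(self):
        g = _gene()
        dmr = GenomicInterval("chr1", 22_000, 22_500)
        (assoc,) = ann.associate_genes(dmr, [g])
        assert assoc.relation == "downstream"
        assert assoc.distance_to_tss == 2000

    def test_beyond_flank_is_empty(self):
        g = _gene()
        dmr = GenomicInterval("chr1", 13_000, 13_500)  # 6.5 kb away
        assert ann.associate_genes(dmr, [g]) == []

    def test_strand_mirror_preserves_relation_and_distance(self):
        # reflecting the DMR about the TSS while flipping the gene strand is
        # the same gene-relative geometry: labels and distances must agree
        plus = _gene(strand="+", span=(20_000, 30_000))       # TSS 20_000
        minus = _gene(strand="-", span=(10_000, 20_000))      # TSS 19_999
        dmr_left = GenomicInterval("chr1", 16_000, 16_500)    # 5' of + TSS
        dmr_right = GenomicInterval("chr1", 23_500, 24_000)   # mirror image
        (ap,) = ann.associate_genes(dmr_left, [plus])
        (am,) = ann.associate_genes(dmr_right, [minus])
        assert ap.relation == am.relation == "upstream"
        assert ap.distance_to_tss == am.distance_to_tss

    def test_minus_strand_sides(self):
        minus = _gene(strand="-", span=(10_000, 20_000))      # TSS 19_999
        above = GenomicInterval("chr1", 21_000, 21_500)
        below = GenomicInterval("chr1", 16_000, 16_500)
        (a,) = ann.associate_genes(above, [minus])
        (b,) = ann.associate_genes(below, [minus])
        assert a.relation == "upstream" and a.distance_to_tss < 0
        assert b.relation == "downstream" and b.distance_to_tss > 0


class TestCpgOe:
    def test_hand_computed_example(self):
        res = ann.cpg_oe("ACGT")
        assert (res.n_cpg, res.n_c, res.n_g, res.length) == (1, 1, 1, 4)
        assert res.oe == 4.0

    def test_no_c_or_g_is_flagged_undefined(self):
        res = ann.cpg_oe("AATT")
        assert not res.defined
        assert res.n_cpg == 0

    def test_n_bases_break_dinucleotides(self):
        with_n = ann.cpg_oe("ACNGT")
        assert with_n.n_cpg == 0
        assert with_n.length == 4  # N excluded

    def test_rejects_non_nucleotides(self):
        with pytest.raises(ValueError):
            ann.cpg_oe("ACGU")

    @given(
        seq=st.text(alphabet="ACGTN", min_size=2, max_size=500),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_naive_recount(self, seq):
        n_cpg, n_c, n_g, length = naive_cpg_counts(seq)
        res = ann.cpg_oe(seq)
        assert (res.n_cpg, res.n_c, res.n_g, res.length) == (
            n_cpg, n_c, n_g, length
        )
        if n_c and n_g:
            assert res.oe == pytest.approx(n_cpg * length / (n_c * n_g))
        else:
            assert not res.defined


class TestCenteredWindow:
    def test_standard_tile_maps_to_itself(self):
        iv = GenomicInterval("chr1", 54_383_000, 54_383_500)
        win = ann.centered_window(iv, chrom_length=60_000_000, window=500)
        assert (win.start, win.end) == (54_383_000, 54_383_500)

    def test_clipped_at_chromosome_edges(self):
        iv = GenomicInterval("chr1", 0, 100)
        win = ann.centered_window(iv, chrom_length=10_000, window=500)
        assert (win.start, win.end) == (0, 500)
        iv = GenomicInterval("chr1", 9_900, 10_000)
        win = ann.centered_window(iv, chrom_length=10_000, window=500)
        assert (win.start, win.end) == (9_500, 10_000)


class TestStratify:
    def test_empty_dmr_list_is_not_an_error(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "category",
                                      "cpg_oe"])
        out = ann.stratify_oe(empty)
        assert set(out["category"]) == {c.value for c in FeatureCategory}
        assert out["n"].sum() == 0

    def test_category_assignment_is_total_and_unique(self, default_sim,
                                                     default_calls):
        config, result = default_sim
        annotated = ann.annotate_dmrs(
            default_calls, result.genes, result.repeats, result.genome
        )
        assert len(annotated) == len(default_calls)
        valid = {c.value for c in FeatureCategory}
        assert set(annotated["category"]) <= valid
        assert annotated["category"].notna().all()
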