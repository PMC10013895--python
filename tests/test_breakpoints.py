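"""Breakpoint annotation: strand-aware feature numbering, fusion
nomination, inversion disruption, span formatting and junction
microhomology."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svsoma.breakpoints import (inversion_disruption, locate_breakpoint,
                                microhomology, nominate_fusions,
                                span_length)
from svsoma.model import GeneModel

from conftest import make_sv


def gene(gene_id, chrom, strand, exons):
    return GeneModel(gene_id=gene_id, gene_name=gene_id, chrom=chrom,
                     strand=strand, exons=tuple(exons))


# a 4-exon template; genomic gaps at 1200-2999, 3200-4999, 5200-6999
EXONS4 = [(1000, 1199), (3000, 3199), (5000, 5199), (7000, 7199)]


class TestLocateBreakpoint:
    def test_plus_strand_second_gap_is_intron_two(self):
        g = gene("g", "chr1", "+", EXONS4)
        assert locate_breakpoint(("chr1", 4000), g) == ("intron", 2)

    def test_minus_strand_counts_from_three_prime_genomic_end(self):
        g = gene("g", "chr1", "-", EXONS4)
        # same genomic gap; transcription runs right to left on minus
        assert locate_breakpoint(("chr1", 4000), g) == ("intron", 2)
        assert locate_breakpoint(("chr1", 2000), g) == ("intron", 3)
        assert locate_breakpoint(("chr1", 1100), g) == ("exon", 4)
        assert locate_breakpoint(("chr1", 7100), g) == ("exon", 1)

    def test_one_bp_past_gene_end_is_outside(self):
        g = gene("g", "chr1", "+", EXONS4)
        assert locate_breakpoint(("chr1", 7200), g) is None
        assert locate_breakpoint(("chr1", 999), g) is None
        assert locate_breakpoint(("chr2", 4000), g) is None

    def test_numbering_invariant_to_flanking_offset(self):
        base = gene("g", "chr1", "+", EXONS4)
        offset = 1_000_000
        shifted = gene("g", "chr1", "+",
                       [(s + offset, e + offset) for s, e in EXONS4])
        assert locate_breakpoint(("chr1", 4000), base) == \
            locate_breakpoint(("chr1", 4000 + offset), shifted)


def rnf38_like():
    # plus strand, 5 exons: intron 3 spans 30600..39999
    exons = [(10_000, 10_200), (20_000, 20_200), (30_400, 30_599),
             (40_000, 40_200), (50_000, 50_200)]
    return gene("RNF38like", "chr9", "+", exons)


def rad51b_like():
    # plus strand, 10 exons spaced 10 kbp apart; intron 8 follows exon 8
    exons = [(100_000 + 10_000 * i, 100_200 + 10_000 * i) for i in range(10)]
    return gene("RAD51Blike", "chr14", "+", exons)


class TestNominateFusions:
    def test_translocation_joining_two_introns(self):
        sv = make_sv("TRA", chrom="chr9", pos=35_000, chrom2="chr14",
                     pos2=175_000, record_id="tra1")
        fusions, disruptions = nominate_fusions(
            [sv], [rnf38_like(), rad51b_like()])
        assert len(fusions) == 1 and not disruptions
        f = fusions[0]
        locations = {f.gene_a: f.bp_a_location, f.gene_b: f.bp_b_location}
        assert locations == {"RNF38like": ("intron", 3),
                             "RAD51Blike": ("intron", 8)}

    def test_inversion_joining_two_genes_on_one_chromosome(self):
        # SMAD3-like: 9 exons on chr15-like coordinates; intron 7 after
        # exon 7. SHISA6-like: 5 exons; intron 3 after exon 3.
        smad3 = gene("SMAD3like", "chr15", "+",
                     [(100_000 + 5_000 * i, 100_300 + 5_000 * i)
                      for i in range(9)])
        shisa6 = gene("SHISA6like", "chr15", "+",
                      [(400_000 + 5_000 * i, 400_300 + 5_000 * i)
                       for i in range(5)])
        sv = make_sv("INV", chrom="chr15", pos=131_000, end=412_000,
                     record_id="inv1")
        fusions, _ = nominate_fusions([sv], [smad3, shisa6])
        assert len(fusions) == 1
        assert fusions[0].bp_a_location == ("intron", 7)
        assert fusions[0].bp_b_location == ("intron", 3)

    def test_deletion_inside_one_gene_yields_disruption_only(self):
        g = rad51b_like()
        sv = make_sv("DEL", chrom="chr14", pos=105_000, end=125_000,
                     record_id="del1")
        fusions, disruptions = nominate_fusions([sv], [g])
        assert not fusions
        assert len(disruptions) == 1
        assert disruptions[0].mode == "BREAKPOINT_IN_GENE"
        assert disruptions[0].gene_id == "RAD51Blike"

    def test_intergenic_breakpoint_yields_single_gene_disruption(self):
        sv = make_sv("DEL", chrom="chr9", pos=35_000, end=900_000,
                     record_id="del2")
        fusions, disruptions = nominate_fusions([sv], [rnf38_like()])
        assert not fusions and len(disruptions) == 1

    def test_insertions_skipped(self):
        sv = make_sv("INS", chrom="chr9", pos=35_000, svlen=100)
        assert nominate_fusions([sv], [rnf38_like()]) == ([], [])

    def test_never_both_fusion_and_disruption_per_sv(self):
        genes = [rnf38_like(), rad51b_like()]
        svs = [make_sv("TRA", chrom="chr9", pos=35_000, chrom2="chr14",
                       pos2=175_000, record_id="f"),
               make_sv("DEL", chrom="chr14", pos=105_000, end=125_000,
                       record_id="d")]
        fusions, disruptions = nominate_fusions(svs, genes)
        assert {f.sv_id for f in fusions} & {d.sv_id for d in disruptions} \
            == set()


class TestInversionDisruption:
    def apc_like(self):
        # first exon inside the inverted span; remaining exons beyond the
        # right breakpoint (gene only partially contained)
        exons = [(112_050_000, 112_050_500)] + [
            (112_100_000 + 8_000 * i, 112_100_400 + 8_000 * i)
            for i in range(14)]
        return gene("APClike", "chr5", "+", exons)

    def test_exon_one_trapped_by_large_inversion(self):
        inv = make_sv("INV", chrom="chr5", pos=107_157_237,
                      end=112_073_107, record_id="apc_inv")
        calls = inversion_disruption(inv, [self.apc_like()])
        assert len(calls) == 1
        assert calls[0].mode == "EXON_CONTAINED"
        assert calls[0].exons_affected == (1,)

    def test_internal_exon_trapped(self):
        # CFTR-like: exon 11 inside an ~11 kbp inversion, neighbours out
        exons = [(117_100_000 + 8_000 * i, 117_100_300 + 8_000 * i)
                 for i in range(10)]
        exons += [(117_195_000, 117_195_250)]  # exon 11 inside the span
        exons += [(117_300_000 + 8_000 * i, 117_300_300 + 8_000 * i)
                  for i in range(5)]
        cftr = gene("CFTRlike", "chr7", "+", exons)
        inv = make_sv("INV", chrom="chr7", pos=117_191_185,
                      end=117_202_321, record_id="cftr_inv")
        calls = inversion_disruption(inv, [cftr])
        assert calls == [calls[0]]
        assert calls[0].exons_affected == (11,)

    def test_fully_contained_gene_lists_all_exons(self):
        g = gene("g", "chr1", "+", EXONS4)
        inv = make_sv("INV", chrom="chr1", pos=500, end=8_000)
        (call,) = inversion_disruption(inv, [g])
        assert call.mode == "EXON_CONTAINED"
        assert call.exons_affected == (1, 2, 3, 4)

    def test_breakpoint_touch_without_trapped_exon(self):
        g = gene("g", "chr1", "+", EXONS4)
        inv = make_sv("INV", chrom="chr1", pos=4_000, end=4_500)
        (call,) = inversion_disruption(inv, [g])
        assert call.mode == "BREAKPOINT_IN_GENE"

    def test_no_overlap_empty(self):
        g = gene("g", "chr1", "+", EXONS4)
        inv = make_sv("INV", chrom="chr1", pos=100_000, end=200_000)
        assert inversion_disruption(inv, [g]) == []

    def test_non_inversion_rejected(self):
        with pytest.raises(ValueError, match="INV"):
            inversion_disruption(make_sv("DEL"), [])


class TestSpanLength:
    def test_multi_megabase_inversion_rounds_to_mbp(self):
        sv = make_sv("INV", chrom="chr5", pos=107_157_237, end=112_073_107)
        bp, label = span_length(sv)
        assert bp == 4_915_870
        assert label == "4.9 Mbp"

    def test_kilobase_inversion(self):
        sv = make_sv("INV", chrom="chr7", pos=117_191_185, end=117_202_321)
        bp, label = span_length(sv)
        assert bp == 11_136
        assert label == "11.1 kbp"

    def test_degenerate_zero_span(self):
        sv = make_sv("INV", pos=500, end=500, svlen=1000)
        sv = sv.copy(end=500)
        assert span_length(sv)[0] == 0

    def test_translocation_rejected(self):
        with pytest.raises(ValueError, match="span"):
            span_length(make_sv("TRA"))


class TestMicrohomology:
    def test_shared_four_bp_junction(self):
        call = microhomology("TTTTACGT", "ACGTCCCC")
        assert (call.length, call.sequence) == (4, "ACGT")
        assert call.mechanism_hint == "MMEJ_LIKE"

    def test_disjoint_flanks_are_blunt(self):
        call = microhomology("AAAA", "CCCC")
        assert call.length == 0
        assert call.mechanism_hint == "BLUNT"

    def test_full_overlap(self):
        assert microhomology("ACGT", "ACGT").length == 4

    def test_single_base_is_blunt_hint(self):
        call = microhomology("AAAC", "CAAA")
        assert call.length == 1
        assert call.mechanism_hint == "BLUNT"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            microhomology("ACGU", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=12),
           st.text(alphabet="ACGT", min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_maximum(self, s1, s2):
        best = max((k for k in range(min(len(s1), len(s2)) + 1)
                    if s1[len(s1) - k:] == s2[:k]), default=0)
        assert microhomology(s1, s2).length == best
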