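"""Data model and file I/O: VCF round trips, ingest filters, gene-model
coordinate conventions and metadata validation."""

import numpy as np
import pytest

from svsoma import io as svio
from svsoma.model import GeneModel, SampleMeta, pair_index

from conftest import make_callset, make_meta, make_sv, random_records

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
##INFO=<ID=CHR2,Number=1,Type=String,Description="c">
##INFO=<ID=RE,Number=1,Type=Integer,Description="r">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="s">
##INFO=<ID=RNAMES,Number=.,Type=String,Description="n">
##contig=<ID=chr1,length=10000000>
##contig=<ID=chr2,length=10000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_text(tmp_path, body, name="in.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestReadSvVcf:
    def test_negative_svlen_stored_absolute(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t5000\td1\tN\t<DEL>\t.\t.\t"
            "SVTYPE=DEL;SVLEN=-120;END=5120;RE=5\n")
        cs = svio.read_sv_vcf(path, make_meta())
        assert len(cs) == 1
        r = cs.records[0]
        assert (r.svtype, r.svlen, r.support) == ("DEL", 120, 5)

    def test_min_size_excludes_small_insertion(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t5000\ti1\tN\t<INS>\t.\t.\t"
            "SVTYPE=INS;SVLEN=40;RE=9\n")
        assert len(svio.read_sv_vcf(path, make_meta(), min_svlen=50)) == 0

    def test_min_support_excludes_single_read_call(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t5000\tv1\tN\t<INV>\t.\t.\t"
            "SVTYPE=INV;SVLEN=200;END=5200;RE=1\n")
        assert len(svio.read_sv_vcf(path, make_meta(), min_support=2)) == 0

    def test_translocation_exempt_from_min_size(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t5000\tt1\tN\t<TRA>\t.\t.\t"
            "SVTYPE=TRA;CHR2=chr2;END=7000;RE=4\n")
        cs = svio.read_sv_vcf(path, make_meta())
        assert len(cs) == 1
        assert cs.records[0].chrom2 == "chr2"
        assert cs.records[0].pos2 == 7000

    def test_missing_svtype_skipped_with_warning(self, tmp_path, caplog):
        path = write_vcf_text(
            tmp_path,
            "chr1\t5000\tok\tN\t<DEL>\t.\t.\tSVTYPE=DEL;SVLEN=-99;RE=5\n"
            "chr1\t6000\tbad\tN\t<DEL>\t.\t.\tSVLEN=-99;RE=5\n")
        with caplog.at_level("WARNING"):
            cs = svio.read_sv_vcf(path, make_meta())
        assert [r.record_id for r in cs] == ["ok"]
        assert any("SVTYPE" in m for m in caplog.messages)

    def test_unparseable_file_is_hard_error(self, tmp_path):
        path = tmp_path / "junk.vcf"
        path.write_text("this is not a VCF\n")
        with pytest.raises(ValueError, match="junk.vcf"):
            svio.read_sv_vcf(str(path), make_meta())

    def test_support_priority_re_then_support_then_rnames(self, tmp_path):
        path = write_vcf_text(
            tmp_path,
            "chr1\t1000\ta\tN\t<DEL>\t.\t.\t"
            "SVTYPE=DEL;SVLEN=-100;RE=7;SUPPORT=3;RNAMES=x,y\n"
            "chr1\t2000\tb\tN\t<DEL>\t.\t.\t"
            "SVTYPE=DEL;SVLEN=-100;SUPPORT=3;RNAMES=x,y\n"
            "chr1\t3000\tc\tN\t<DEL>\t.\t.\t"
            "SVTYPE=DEL;SVLEN=-100;RNAMES=x,y,z\n")
        cs = svio.read_sv_vcf(path, make_meta())
        assert [r.support for r in cs] == [7, 3, 3]

    def test_bnd_mates_collapse_to_one_junction(self, tmp_path):
        path = write_vcf_text(
            tmp_path,
            "chr1\t5000\tbnd1\tN\tN[chr2:9000[\t.\t.\tSVTYPE=BND;RE=6\n"
            "chr2\t9000\tbnd2\tN\t]chr1:5000]N\t.\t.\tSVTYPE=BND;RE=6\n")
        cs = svio.read_sv_vcf(path, make_meta())
        assert len(cs) == 1
        r = cs.records[0]
        assert (r.svtype, r.chrom, r.pos, r.chrom2, r.pos2) == (
            "TRA", "chr1", 5000, "chr2", 9000)

    def test_symbolic_insertion_without_sequence_accepted(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t5000\ti\tN\t<INS>\t.\t.\t"
            "SVTYPE=INS;SVLEN=200;RE=8\n")
        cs = svio.read_sv_vcf(path, make_meta())
        assert cs.records[0].seq is None


class TestVcfRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        cs = make_callset(random_records(rng, 40))
        path = str(tmp_path / "rt.vcf")
        svio.write_sv_vcf(cs, path)
        back = svio.read_sv_vcf(path, cs.sample)
        assert len(back) == len(cs)
        for a, b in zip(cs, back):
            assert (a.record_id, a.chrom, a.pos, a.end, a.svtype, a.svlen,
                    a.support, a.seq, a.chrom2, a.pos2) == (
                b.record_id, b.chrom, b.pos, b.end, b.svtype, b.svlen,
                b.support, b.seq, b.chrom2, b.pos2)

    def test_empty_callset_writes_header_only_vcf(self, tmp_path):
        path = str(tmp_path / "empty.vcf")
        svio.write_sv_vcf(make_callset([]), path)
        lines = open(path).read().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert len(svio.read_sv_vcf(path, make_meta())) == 0

    def test_translocation_partner_round_trips(self, tmp_path):
        cs = make_callset([make_sv("TRA", chrom="chr1", pos=100_000,
                                   chrom2="chr2", pos2=5_000)])
        path = str(tmp_path / "tra.vcf")
        svio.write_sv_vcf(cs, path)
        text = open(path).read()
        assert "CHR2=chr2" in text
        back = svio.read_sv_vcf(path, cs.sample)
        # canonical orientation: lowest (chrom, pos) first
        assert (back.records[0].chrom, back.records[0].pos) == ("chr1", 100_000)
        assert (back.records[0].chrom2, back.records[0].pos2) == ("chr2", 5_000)

    def test_ingest_filtering_is_idempotent(self, tmp_path, rng):
        cs = make_callset(random_records(rng, 60))
        p1, p2 = str(tmp_path / "a.vcf"), str(tmp_path / "b.vcf")
        svio.write_sv_vcf(cs, p1)
        once = svio.read_sv_vcf(p1, cs.sample)
        svio.write_sv_vcf(once, p2)
        twice = svio.read_sv_vcf(p2, cs.sample)
        assert [r.record_id for r in once] == [r.record_id for r in twice]


class TestGeneModels:
    def test_bed12_blocks_become_exons(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t999\t3000\tGENE1\t0\t+\t999\t3000\t0\t3\t"
                        "100,150,200\t0,500,1801\n")
        (gene,) = svio.read_gene_models(str(path))
        assert gene.n_exons == 3
        # 0-based 999 -> 1-based 1000
        assert gene.exons[0] == (1000, 1099)
        assert gene.exons == ((1000, 1099), (1500, 1649), (2801, 3000))

    def test_minus_strand_intron_one_is_last_genomic_gap(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t0\t5000\tG\t0\t-\t0\t5000\t0\t3\t"
                        "100,100,100\t0,2000,4900\n")
        (gene,) = svio.read_gene_models(str(path))
        # genomic gaps: gap0 (after first exon), gap1; transcription order
        # reverses on the minus strand
        assert gene.intron_number(1) == 1
        assert gene.intron_number(0) == 2
        assert gene.exon_number(2) == 1

    def test_gff3_exons_grouped_by_gene(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1000\t5000\t.\t+\t.\tID=g1;Name=GENEA\n"
            "chr1\tsrc\tmRNA\t1000\t5000\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1000\t1200\t.\t+\t.\tID=e1;Parent=t1\n"
            "chr1\tsrc\texon\t3000\t3200\t.\t+\t.\tID=e2;Parent=t1\n"
            "chr1\tsrc\texon\t4800\t5000\t.\t+\t.\tID=e3;Parent=t1\n")
        (gene,) = svio.read_gene_models(str(path))
        assert gene.gene_name == "GENEA"
        assert gene.exons == ((1000, 1200), (3000, 3200), (4800, 5000))

    def test_zero_exon_gene_is_hard_error(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t0\t100\tG\t0\t+\t0\t100\t0\t0\t\t\n")
        with pytest.raises(ValueError, match="no exons"):
            svio.read_gene_models(str(path))

    def test_gene_model_rejects_overlapping_exons(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel(gene_id="g", gene_name="g", chrom="chr1", strand="+",
                      exons=((100, 300), (200, 400)))


class TestMetadata:
    def _table(self, n_patients=21):
        lines = ["sample_id\tpatient_id\trole\tmean_depth\tmsi_status\tstage"]
        for i in range(n_patients):
            lines.append(f"P{i}-T\tP{i}\ttumor\t17.3\tMSS\tII")
            lines.append(f"P{i}-N\tP{i}\tnormal\t18.1\tMSS\tII")
        return "\n".join(lines) + "\n"

    def test_full_cohort_pairs(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(self._table(21))
        metas = svio.read_metadata(str(path))
        assert len(metas) == 42
        assert len(pair_index(metas)) == 21
        assert metas[0].mean_depth == pytest.approx(17.3)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "sample_id\tpatient_id\trole\tmean_depth\n"
            "S1\tP1\ttumor\t20\nS1\tP1\tnormal\t20\n")
        with pytest.raises(ValueError, match="duplicate"):
            svio.read_metadata(str(path))

    def test_patient_missing_normal_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tpatient_id\trole\tmean_depth\n"
                        "S1\tP1\ttumor\t20\n")
        with pytest.raises(ValueError, match="P1"):
            svio.read_metadata(str(path))

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError, match="mean_depth"):
            SampleMeta(sample_id="S", patient_id="P", role="tumor",
                       mean_depth=0.0)
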