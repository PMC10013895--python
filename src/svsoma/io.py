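"""Readers and writers for the pipeline's file formats.

Formats handled: SV VCF in the Sniffles dialect (SVTYPE/SVLEN/END/CHR2
INFO keys, read support in RE, SUPPORT or RNAMES), BED12 and GFF3 gene
models, repeat-region BED tracks, repeat-library FASTA, and the
tab-separated sample-metadata table.

Internal coordinates are 1-based inclusive (VCF convention); BED's
0-based half-open coordinates are converted here and nowhere else.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .model import (MIN_SUPPORT, MIN_SVLEN, MOBILE_CLASSES, REGION_CLASSES,
                    Callset, GeneModel, RepeatClass, RepeatEntry,
                    RepeatLibrary, SampleMeta, SVRecord, pair_index)

log = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "patient_id", "role", "mean_depth",
                    "msi_status", "stage"]


# ---------------------------------------------------------------------------
# SV VCF

def _parse_breakend_alt(alt: str) -> Optional[tuple[str, int]]:
    """Extract the partner locus from a BND ALT like ``N[chr2:321[``."""
    for bracket in "[]":
        if bracket in alt:
            try:
                inner = alt.split(bracket)[1]
                chrom2, pos2 = inner.rsplit(":", 1)
                return chrom2, int(pos2)
            except (IndexError, ValueError):
                return None
    return None


def _record_support(info, n_alleles_hint: Optional[int] = None) -> Optional[int]:
    """Read support: RE, then SUPPORT, then the RNAMES entry count."""
    for key in ("RE", "SUPPORT"):
        if key in info:
            val = info[key]
            if isinstance(val, (tuple, list)):
                val = val[0]
            return int(val)
    if "RNAMES" in info:
        val = info["RNAMES"]
        if isinstance(val, (tuple, list)):
            return len(val)
        return len(str(val).split(","))
    return None


def read_sv_vcf(path: str, sample: SampleMeta,
                min_support: int = MIN_SUPPORT,
                min_svlen: int = MIN_SVLEN) -> Callset:
    """Load a Sniffles-dialect SV VCF and apply the ingest filters.

    Records are kept only with ``support >= min_support`` and, for
    non-translocation types, ``|SVLEN| >= min_svlen``. Negative SVLEN
    (Sniffles deletions) is stored as an absolute length. Breakend (BND)
    mate pairs and duplicate TRA junctions are collapsed to a single
    record per junction, lowest (chrom, pos) first.
    """
    records: list[SVRecord] = []
    seen_junctions: set[tuple] = set()
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf):
            info = rec.info
            if "SVTYPE" not in info:
                log.warning("%s line %d (%s): no SVTYPE, record skipped",
                            path, i + 1, rec.id or ".")
                continue
            svtype = str(info["SVTYPE"])
            if isinstance(info.get("SVTYPE"), tuple):
                svtype = str(info["SVTYPE"][0])
            chrom2 = pos2 = None
            if svtype in ("BND", "TRA"):
                svtype = "TRA"
                if "CHR2" in info:
                    chrom2 = str(info["CHR2"])
                    pos2 = int(rec.stop)
                    if "POS2" in info:
                        pos2 = int(info["POS2"])
                else:
                    partner = _parse_breakend_alt(str(rec.alts[0]))
                    if partner is None:
                        log.warning("%s line %d: BND without partner locus, "
                                    "record skipped", path, i + 1)
                        continue
                    chrom2, pos2 = partner
            if svtype not in ("DEL", "INS", "DUP", "INV", "TRA"):
                log.warning("%s line %d: unsupported SVTYPE %s, skipped",
                            path, i + 1, svtype)
                continue
            svlen = info.get("SVLEN", 0)
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            svlen = abs(int(svlen or 0))
            support = _record_support(info)
            if support is None:
                log.warning("%s line %d: no RE/SUPPORT/RNAMES, skipped",
                            path, i + 1)
                continue
            seq = None
            if "SEQ" in info:
                seq = str(info["SEQ"])
            elif svtype == "INS" and rec.alts and set(rec.alts[0]) <= set("ACGTNacgtn"):
                if len(rec.alts[0]) > len(rec.ref):
                    seq = str(rec.alts[0])[len(rec.ref):]
            if support < min_support:
                continue
            if svtype != "TRA" and svlen < min_svlen:
                continue
            end = int(rec.stop) if svtype in ("DEL", "DUP", "INV") else None
            if end is not None and end <= rec.pos:
                end = rec.pos + svlen
            sv = SVRecord(
                record_id=rec.id or f"{sample.sample_id}_{i}",
                sample_id=sample.sample_id,
                chrom=str(rec.chrom), pos=int(rec.pos), end=end,
                chrom2=chrom2, pos2=pos2,
                svtype=svtype, svlen=svlen, support=support, seq=seq)
            if sv.svtype == "TRA":
                key = (sv.chrom, sv.pos, sv.chrom2, sv.pos2)
                if key in seen_junctions:
                    continue
                seen_junctions.add(key)
            records.append(sv)
    return Callset(sample=sample, records=records)


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the SV">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the SV">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome of a translocation">',
    '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Partner position of a translocation">',
    '##INFO=<ID=RE,Number=1,Type=Integer,Description="Number of supporting reads">',
    '##INFO=<ID=SEQ,Number=1,Type=String,Description="Variant sequence">',
    '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Call absent from the matched normal">',
    '##INFO=<ID=CLUSTER_ID,Number=1,Type=String,Description="Cohort merge cluster">',
    '##INFO=<ID=RECURRENCE,Number=1,Type=Integer,Description="Distinct patients carrying the cluster">',
]


def _vcf_header(contigs: Iterable[str],
                contig_lengths: Optional[dict[str, int]] = None
                ) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            header.add_line(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            header.add_line(f"##contig=<ID={c}>")
    return header


def write_sv_vcf(callset: Callset, path: str,
                 contig_lengths: Optional[dict[str, int]] = None,
                 extra_info: Optional[dict[str, dict]] = None) -> None:
    """Write a callset as a VCF 4.2 file that round-trips through
    :func:`read_sv_vcf` record-for-record.

    ``extra_info`` optionally maps record_id to additional INFO fields
    (used for cluster ids and recurrence in the merged cohort VCF).
    """
    contigs: list[str] = []
    for r in callset:
        for c in (r.chrom, r.chrom2):
            if c is not None and c not in contigs:
                contigs.append(c)
    if contig_lengths:
        contigs = sorted(set(contigs) | set(contig_lengths),
                         key=lambda c: (len(c), c))
    header = _vcf_header(contigs, contig_lengths)
    try:
        out = pysam.VariantFile(path, "w", header=header)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot write VCF to {path!r}: {exc}") from exc
    with out:
        for r in callset:
            stop = r.end if r.svtype in ("DEL", "DUP", "INV") else r.pos
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=stop,
                alleles=("N", f"<{r.svtype}>"), id=r.record_id)
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = -r.svlen if r.svtype == "DEL" else r.svlen
            rec.info["RE"] = r.support
            if r.svtype == "TRA":
                rec.info["CHR2"] = r.chrom2
                rec.info["POS2"] = r.pos2
            if r.seq:
                rec.info["SEQ"] = r.seq
            if callset.somatic:
                rec.info["SOMATIC"] = True
            if extra_info and r.record_id in extra_info:
                for k, v in extra_info[r.record_id].items():
                    rec.info[k] = v
            out.write(rec)


# ---------------------------------------------------------------------------
# Gene models

def _read_bed12(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path} line {lineno}: BED12 requires 12 columns")
            chrom, start0, _end0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if fields[5] in "+-" else "+"
            n_blocks = int(fields[9])
            if n_blocks == 0:
                raise ValueError(f"{path} line {lineno}: gene {name} has no exons")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(
                    f"{path} line {lineno}: blockCount disagrees with blocks")
            exons = [(start0 + s + 1, start0 + s + sz)
                     for s, sz in zip(starts, sizes)]
            if exons != sorted(exons):
                log.warning("%s line %d: exons of %s out of order, sorting",
                            path, lineno, name)
                exons.sort()
            genes.append(GeneModel(gene_id=name, gene_name=name, chrom=chrom,
                                   strand=strand, exons=tuple(exons)))
    return genes


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        intervals = sorted((f.start, f.end)
                           for f in db.children(gene, featuretype="exon"))
        if not intervals:
            raise ValueError(f"{path}: gene {gene.id} has no exons")
        # merge overlapping exons across transcripts
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        name = gene.attributes.get("Name", [gene.id])[0]
        genes.append(GeneModel(gene_id=gene.id, gene_name=name,
                               chrom=gene.seqid, strand=gene.strand,
                               exons=tuple(tuple(x) for x in merged)))
    return genes


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3 (auto-detected)."""
    lower = path.lower()
    if lower.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    if lower.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return _read_gff3(path)
            if line.strip() and not line.startswith("#"):
                break
    return _read_bed12(path)


# ---------------------------------------------------------------------------
# Sample metadata

def read_metadata(path: str) -> list[SampleMeta]:
    """Read the tab-separated sample table and validate tumor/normal
    pairing (exactly one of each per patient)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "patient_id", "role", "mean_depth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(SampleMeta(
            sample_id=row["sample_id"], patient_id=row["patient_id"],
            role=row["role"], mean_depth=float(row["mean_depth"]),
            msi_status=row.get("msi_status", "MSS") or "MSS",
            stage=row.get("stage", "unknown") or "unknown"))
    pair_index(metas)  # raises on incomplete pairs / duplicate ids
    return metas


def write_metadata(metas: Iterable[SampleMeta], path: str) -> None:
    rows = [{c: getattr(m, c) for c in METADATA_COLUMNS} for m in metas]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Repeat regions and repeat library

def read_repeat_regions(path: str) -> dict[str, IntervalTree]:
    """Read a repeat-region BED (class name in column 4) into per-chrom
    interval trees keyed on 1-based positions."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path} line {lineno}: repeat BED needs 4 columns")
            chrom, start0, end0, cls = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if cls not in REGION_CLASSES:
                raise ValueError(
                    f"{path} line {lineno}: unknown repeat class {cls!r}")
            trees.setdefault(chrom, IntervalTree()).addi(
                start0 + 1, end0 + 1, REGION_CLASSES[cls])
    return trees


def region_class_at(trees: dict[str, IntervalTree], chrom: str,
                    pos: int) -> Optional[RepeatClass]:
    """Repeat class of the region covering a 1-based position, if any."""
    tree = trees.get(chrom)
    if tree is None:
        return None
    hits = tree[pos]
    if not hits:
        return None
    # deterministic tie-break: smallest interval first, then class name
    best = min(hits, key=lambda iv: (iv.end - iv.begin, iv.data.value))
    return best.data


def read_repeat_library(path: str) -> RepeatLibrary:
    """Read a repeat-consensus FASTA with ``name#CLASS`` headers."""
    entries = []
    for rec in SeqIO.parse(path, "fasta"):
        if "#" not in rec.id:
            raise ValueError(
                f"{path}: header {rec.id!r} lacks the name#CLASS form")
        name, cls = rec.id.rsplit("#", 1)
        if cls not in MOBILE_CLASSES:
            raise ValueError(f"{path}: unknown mobile-element class {cls!r}")
        entries.append(RepeatEntry(name=name,
                                   repeat_class=MOBILE_CLASSES[cls],
                                   consensus=str(rec.seq).upper()))
    return RepeatLibrary(entries=entries)


def write_repeat_library(library: RepeatLibrary, path: str) -> None:
    recs = [SeqRecord(Seq(e.consensus),
                      id=f"{e.name}#{e.repeat_class.name}", description="")
            for e in library]
    SeqIO.write(recs, path, "fasta")


def write_fasta(sequences: dict[str, str], path: str) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in sequences.items()]
    SeqIO.write(recs, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
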