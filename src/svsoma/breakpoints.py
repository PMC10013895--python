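"""Breakpoint-consequence annotation against gene models.

Covers four questions about a somatic SV: which gene feature each
breakpoint falls in (strand-aware exon/intron numbering), whether the
two breakpoints of one SV nominate a candidate gene fusion, which exons
an inversion traps inside its span, and how much microhomology the two
junction flanks share (>=2 bp being consistent with MMEJ).
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .model import (DisruptionCall, FusionCandidate, GeneModel,
                    MicrohomologyCall, SVRecord)

_VALID_BASES = frozenset("ACGTN")


def locate_breakpoint(pos: tuple[str, int], gene: GeneModel
                      ) -> Optional[tuple[str, int]]:
    """Locate a breakpoint within a gene.

    Returns ``("exon", k)`` or ``("intron", k)`` with ``k`` numbered in
    transcription order (on the minus strand exon 1 is the genomically
    last exon), or ``None`` when the position lies outside the gene
    span or on another chromosome.
    """
    chrom, coord = pos
    if chrom != gene.chrom or not gene.start <= coord <= gene.end:
        return None
    starts = [s for s, _ in gene.exons]
    i = bisect_right(starts, coord) - 1
    if i >= 0 and gene.exons[i][0] <= coord <= gene.exons[i][1]:
        return ("exon", gene.exon_number(i))
    # coord sits in the genomic gap after exon i
    return ("intron", gene.intron_number(i))


def _gene_index(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    return trees


def _gene_at(trees: dict[str, IntervalTree], chrom: str,
             coord: int) -> Optional[GeneModel]:
    tree = trees.get(chrom)
    if tree is None:
        return None
    hits = sorted(tree[coord], key=lambda iv: (iv.begin, iv.data.gene_id))
    return hits[0].data if hits else None


def _sv_breakpoints(sv: SVRecord) -> tuple[tuple[str, int], tuple[str, int]]:
    if sv.svtype == "TRA":
        return (sv.chrom, sv.pos), (sv.chrom2, sv.pos2)
    return (sv.chrom, sv.pos), (sv.chrom, sv.end)


def nominate_fusions(svs: Iterable[SVRecord],
                     genes: Iterable[GeneModel],
                     ) -> tuple[list[FusionCandidate], list[DisruptionCall]]:
    """Nominate fusion candidates: SVs whose two breakpoints land in two
    different genes.

    Insertions are skipped (single breakpoint). An SV with both
    breakpoints in the same gene, or with only one genic breakpoint,
    yields a ``BREAKPOINT_IN_GENE`` disruption instead of a candidate;
    fully intergenic SVs yield nothing. Candidates are structural
    nominations only — they carry no expression evidence.
    """
    trees = _gene_index(genes)
    fusions: list[FusionCandidate] = []
    disruptions: list[DisruptionCall] = []
    for sv in svs:
        if sv.svtype == "INS":
            continue
        bp1, bp2 = _sv_breakpoints(sv)
        g1 = _gene_at(trees, *bp1)
        g2 = _gene_at(trees, *bp2)
        if g1 is not None and g2 is not None and g1.gene_id != g2.gene_id:
            loc1 = locate_breakpoint(bp1, g1)
            loc2 = locate_breakpoint(bp2, g2)
            note = (f"{sv.svtype}: upstream of {loc1[0]} {loc1[1]} of "
                    f"{g1.gene_name} joined to downstream of {loc2[0]} "
                    f"{loc2[1]} of {g2.gene_name}")
            fusions.append(FusionCandidate(
                sv_id=sv.record_id, gene_a=g1.gene_id, gene_b=g2.gene_id,
                bp_a_location=loc1, bp_b_location=loc2,
                orientation_note=note))
        else:
            for gene, bp in ((g1, bp1), (g2, bp2)):
                if gene is not None:
                    disruptions.append(DisruptionCall(
                        sv_id=sv.record_id, gene_id=gene.gene_id,
                        mode="BREAKPOINT_IN_GENE"))
                    break  # one disruption per SV in the same-gene case
    return fusions, disruptions


def inversion_disruption(inv: SVRecord, genes: Iterable[GeneModel]
                         ) -> list[DisruptionCall]:
    """Report genes whose structure an inversion breaks.

    A gene overlapping the inverted span is reported ``EXON_CONTAINED``
    with the transcription-order numbers of the exons lying fully
    inside the span (all exons when the whole gene is contained — its
    orientation relative to flanking sequence still flips). A gene that
    overlaps the span but contributes no fully contained exon is merely
    touched by a breakpoint: ``BREAKPOINT_IN_GENE``.
    """
    if inv.svtype != "INV":
        raise ValueError(f"{inv.record_id}: expected INV, got {inv.svtype}")
    calls: list[DisruptionCall] = []
    for gene in genes:
        if gene.chrom != inv.chrom:
            continue
        if gene.end < inv.pos or gene.start > inv.end:
            continue
        inside = tuple(
            gene.exon_number(i) for i, (s, e) in enumerate(gene.exons)
            if inv.pos <= s and e <= inv.end)
        if inside:
            calls.append(DisruptionCall(
                sv_id=inv.record_id, gene_id=gene.gene_id,
                mode="EXON_CONTAINED", exons_affected=tuple(sorted(inside))))
        else:
            calls.append(DisruptionCall(
                sv_id=inv.record_id, gene_id=gene.gene_id,
                mode="BREAKPOINT_IN_GENE"))
    return calls


def span_length(sv: SVRecord) -> tuple[int, str]:
    """Breakpoint-to-breakpoint span of an intrachromosomal SV.

    Returns ``end - pos`` in bp together with a human-readable form
    rounded to one decimal: Mbp at or above 1 Mbp, kbp below.
    """
    if sv.svtype == "TRA":
        raise ValueError(f"{sv.record_id}: translocations have no span")
    bp = sv.end - sv.pos
    if bp >= 1_000_000:
        label = f"{bp / 1_000_000:.1f} Mbp"
    else:
        label = f"{bp / 1_000:.1f} kbp"
    return bp, label


def microhomology(junction_side_1: str, junction_side_2: str,
                  sv_id: str = "") -> MicrohomologyCall:
    """Longest sequence shared as a suffix of side 1 and a prefix of
    side 2 of a rearrangement junction.

    >=2 bp of microhomology is hinted as MMEJ-like; 0-1 bp junctions
    are treated as blunt.
    """
    s1 = junction_side_1.upper()
    s2 = junction_side_2.upper()
    if not s1 or not s2:
        raise ValueError("both junction flanks must be non-empty")
    for s in (s1, s2):
        if not set(s) <= _VALID_BASES:
            bad = sorted(set(s) - _VALID_BASES)
            raise ValueError(f"non-nucleotide characters in flank: {bad}")
    best = 0
    for k in range(1, min(len(s1), len(s2)) + 1):
        if s1[-k:] == s2[:k]:
            best = k
    seq = s1[-best:] if best else ""
    hint = "MMEJ_LIKE" if best >= 2 else "BLUNT"
    return MicrohomologyCall(sv_id=sv_id, length=best, sequence=seq,
                             mechanism_hint=hint)
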