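"""Core data model for somatic structural-variant (SV) analysis.

Coordinates are 1-based inclusive throughout, matching VCF POS/END; BED
input is converted at the I/O boundary. An SV call is the atom of every
pipeline stage: ingest filtering, tumor-normal subtraction, cohort
merging, repeat classification and breakpoint annotation all operate on
:class:`SVRecord`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")

#: Minimum SV size used at ingest (bp); translocations are exempt.
MIN_SVLEN = 50
#: Minimum number of supporting reads used at ingest.
MIN_SUPPORT = 2


class RepeatClass(str, enum.Enum):
    """Repeat-content class of an insertion/deletion sequence or locus."""

    STR = "STR"
    TANDEM_REPEAT = "Tandem_repeat"
    LINE = "LINE"
    SINE = "SINE"
    LTR = "LTR"
    SEGDUP = "Segdup"
    SATELLITE = "Satellite"
    LOW_COMPLEXITY = "Low_complexity"
    NONE = "None"
    UNCLASSIFIABLE = "Unclassifiable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes that can be assigned from a repeat-region track (BED column 4).
REGION_CLASSES = {
    "STR": RepeatClass.STR,
    "Segdup": RepeatClass.SEGDUP,
    "Satellite": RepeatClass.SATELLITE,
    "Low_complexity": RepeatClass.LOW_COMPLEXITY,
}

#: Mobile-element classes carried by a consensus library.
MOBILE_CLASSES = {"LINE": RepeatClass.LINE, "SINE": RepeatClass.SINE,
                  "LTR": RepeatClass.LTR}


@dataclass
class SVRecord:
    """A single structural-variant call.

    ``pos``/``end`` bracket the affected span for DEL/DUP/INV. For INS
    the convention ``end == pos`` holds (single breakpoint). For TRA the
    partner locus lives in ``chrom2``/``pos2`` and ``end`` is ignored.
    ``support`` is the number of reads evidencing the call (Sniffles RE).
    """

    record_id: str
    sample_id: str
    chrom: str
    pos: int
    svtype: str
    svlen: int
    support: int
    end: Optional[int] = None
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        self.svlen = abs(int(self.svlen))
        if self.svtype == "INS":
            self.end = self.pos
        elif self.svtype == "TRA":
            if self.chrom2 is None or self.pos2 is None:
                raise ValueError(f"{self.record_id}: TRA requires chrom2/pos2")
            # canonical junction orientation: lowest (chrom, pos) first
            if (self.chrom2, self.pos2) < (self.chrom, self.pos):
                self.chrom, self.chrom2 = self.chrom2, self.chrom
                self.pos, self.pos2 = self.pos2, self.pos
        else:
            if self.end is None:
                self.end = self.pos + self.svlen
            if self.pos > self.end:
                raise ValueError(
                    f"{self.record_id}: pos {self.pos} > end {self.end}")

    @property
    def span(self) -> int:
        """Interval span in bp (end - pos + 1) for spanning types."""
        if self.svtype in ("DEL", "DUP", "INV"):
            return self.end - self.pos + 1
        return 0

    def copy(self, **changes) -> "SVRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: pairing, depth and tumor phenotype."""

    sample_id: str
    patient_id: str
    role: str  # "tumor" | "normal"
    mean_depth: float
    msi_status: str = "MSS"  # "MSI-H" | "MSS"
    stage: str = "unknown"  # "II" | "III" | "unknown"

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "normal"):
            raise ValueError(f"role must be tumor/normal, got {self.role!r}")
        if self.mean_depth <= 0:
            raise ValueError(f"{self.sample_id}: mean_depth must be > 0")
        if self.msi_status not in ("MSI-H", "MSS"):
            raise ValueError(f"bad msi_status {self.msi_status!r}")


@dataclass
class Callset:
    """All SV calls of one sample, sorted by (chrom, pos)."""

    sample: SampleMeta
    records: list[SVRecord] = field(default_factory=list)
    somatic: bool = False

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.records.sort(key=lambda r: (r.chrom, r.pos, r.record_id))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class MatchParams:
    """Thresholds for SV matching, filtering and subtraction.

    Defaults: breakpoints within 1 kbp for all types, >=40% reciprocal
    overlap for DEL/INV/DUP, <20% relative length difference, tumor calls
    kept at support >= 0.3x the sample's mean depth, normal calls counted
    as evidence at >= 2 supporting reads.
    """

    max_dist: int = 1000
    min_reciprocal_overlap: float = 0.40
    max_len_diff_frac: float = 0.20
    depth_support_frac: float = 0.3
    min_normal_support: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.min_reciprocal_overlap <= 1:
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")
        if not 0 <= self.max_len_diff_frac < 1:
            raise ValueError("max_len_diff_frac must be in [0, 1)")
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")


@dataclass
class MergedSV:
    """A cross-sample cluster of matching SV calls."""

    cluster_id: str
    members: list[SVRecord]
    representative: SVRecord
    recurrence: int  # number of distinct patients contributing a member
    svtype: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(f"{self.cluster_id}: representative not a member")
        if self.recurrence < 1:
            raise ValueError(f"{self.cluster_id}: recurrence must be >= 1")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware exon structure.

    Exons are 1-based inclusive ``(start, end)`` intervals sorted by
    genomic start. Intron ``k`` lies between exon ``k`` and exon ``k+1``
    in *transcription* order: on the minus strand exon 1 is the
    genomically last exon, so intron numbering runs right to left.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} inverted")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_number(self, genomic_index: int) -> int:
        """Transcription-order exon number for a 0-based genomic index."""
        if self.strand == "+":
            return genomic_index + 1
        return self.n_exons - genomic_index

    def intron_number(self, genomic_gap_index: int) -> int:
        """Transcription-order intron number for a 0-based genomic gap."""
        if self.strand == "+":
            return genomic_gap_index + 1
        return self.n_exons - 1 - genomic_gap_index


@dataclass(frozen=True)
class FusionCandidate:
    """An SV whose two breakpoints land in two different genes."""

    sv_id: str
    gene_a: str
    gene_b: str
    bp_a_location: tuple[str, int]  # (feature "exon"|"intron", index)
    bp_b_location: tuple[str, int]
    orientation_note: str = ""

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("fusion requires two distinct genes")


@dataclass(frozen=True)
class DisruptionCall:
    """A gene whose structure is broken by an SV."""

    sv_id: str
    gene_id: str
    mode: str  # "EXON_CONTAINED" | "BREAKPOINT_IN_GENE"
    exons_affected: tuple[int, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.mode == "EXON_CONTAINED" and not self.exons_affected:
            raise ValueError("EXON_CONTAINED requires affected exons")


@dataclass(frozen=True)
class MicrohomologyCall:
    """Shared sequence at a rearrangement junction.

    >=2 bp of microhomology is flagged as consistent with
    microhomology-mediated end joining (MMEJ); shorter junctions are
    treated as blunt.
    """

    sv_id: str
    length: int
    sequence: str
    mechanism_hint: str  # "MMEJ_LIKE" | "BLUNT"

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with length field")


@dataclass(frozen=True)
class TandemRepeatCall:
    """A tandem-repeat array detected in a variant sequence."""

    motif: str
    copy_number: float
    covered_fraction: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.motif) <= 100:
            raise ValueError("motif period must be 1-100 bp")
        if self.copy_number < 2:
            raise ValueError("copy_number must be >= 2")
        if not 0 < self.covered_fraction <= 1:
            raise ValueError("covered_fraction must be in (0, 1]")

    @property
    def repeat_class(self) -> RepeatClass:
        """STR for microsatellite motifs (<=6 bp), else Tandem_repeat."""
        return (RepeatClass.STR if len(self.motif) <= 6
                else RepeatClass.TANDEM_REPEAT)


@dataclass(frozen=True)
class RepeatEntry:
    name: str
    repeat_class: RepeatClass
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 50:
            raise ValueError(f"{self.name}: consensus shorter than 50 bp")


@dataclass
class RepeatLibrary:
    """A small library of repeat consensus sequences (L1/Alu/LTR-like)."""

    entries: list[RepeatEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate entry names in repeat library")

    def __iter__(self) -> Iterator[RepeatEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def pair_index(metas: Iterable[SampleMeta]) -> dict[str, dict[str, SampleMeta]]:
    """Index samples by patient, checking one tumor + one normal each.

    Returns ``{patient_id: {"tumor": meta, "normal": meta}}``; raises if
    any patient is missing a member of the pair or a sample id repeats.
    """
    metas = list(metas)
    seen: set[str] = set()
    for m in metas:
        if m.sample_id in seen:
            raise ValueError(f"duplicate sample_id {m.sample_id!r}")
        seen.add(m.sample_id)
    index: dict[str, dict[str, SampleMeta]] = {}
    for m in metas:
        slot = index.setdefault(m.patient_id, {})
        if m.role in slot:
            raise ValueError(
                f"patient {m.patient_id!r} has two {m.role} samples")
        slot[m.role] = m
    incomplete = sorted(p for p, s in index.items() if len(s) != 2)
    if incomplete:
        raise ValueError(
            "patients missing a tumor or normal sample: "
            + ", ".join(incomplete))
    return index
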