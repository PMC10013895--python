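"""Synthetic reference and tumor/normal SV-callset simulator.

The simulator emulates the statistical structure of a paired
tumor/normal long-read SV study at desk scale: a small multi-chromosome
reference carrying planted STR arrays and mobile-element copies
(LINE/SINE/LTR-like consensus library), multi-exon gene models, and per
patient a germline callset shared by both samples plus tumor-only
somatic calls. Microsatellite-unstable (MSI-H) tumors receive a large
multiplicative burst of somatic STR-expansion insertions, mirroring the
insertion dominance of MSI-H colorectal tumors. Observation noise
covers breakpoint jitter, binomial read support at the sample's depth,
per-call dropout and uniformly placed false-positive calls.

Every emitted call traces to a ground-truth event (or is flagged as a
false positive) in a :class:`SimTruth` ledger, so pipeline recovery is
measurable exactly.

Deliberate simplifications: somatic events are placed at loci distinct
from the same patient's germline events (a somatic change at a locus
already carrying a germline call is not representable at callset
level); spanning-type (DEL/DUP/INV) lengths start at 3 kbp so that the
100 bp breakpoint scatter stays well inside the 20% length-matching
band; deletions carry no sequence (as long-read callers emit them) and
are classified by locus.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as svio
from .model import (Callset, GeneModel, RepeatClass, RepeatEntry,
                    RepeatLibrary, SampleMeta, SVRecord)
from .somatic import _breakpoint_distance, _MatchIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator, with study-scale defaults.

    Depth defaults to 20x (the cohort being emulated averaged ~17-25x);
    per-patient event counts are Poisson-distributed around the stated
    means (200 germline + 50 somatic calls split across the five SV
    types). ``msi_h_fraction`` of patients are MSI-H and their somatic
    STR-insertion mean is multiplied by ``msi_str_ins_boost``.
    """

    seed: int = 0
    # reference
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    str_region_count: int = 150
    str_motif_len_range: tuple[int, int] = (1, 6)
    str_copies_range: tuple[int, int] = (20, 80)
    mobile_element_copies: dict = field(
        default_factory=lambda: {"LINE": 30, "SINE": 40, "LTR": 20})
    other_region_count: int = 5  # per Segdup/Satellite/Low_complexity class
    genes_per_chromosome: int = 6
    # cohort
    n_patients: int = 10
    germline_counts: dict = field(
        default_factory=lambda: {"DEL": 80, "INS": 80, "DUP": 15,
                                 "INV": 15, "TRA": 10})
    somatic_counts: dict = field(
        default_factory=lambda: {"DEL": 20, "INS": 15, "DUP": 5,
                                 "INV": 5, "TRA": 5})
    ins_str_fraction: float = 1 / 3  # of insertion events, before any boost
    ins_mobile_fractions: dict = field(
        default_factory=lambda: {"LINE": 0.35, "SINE": 0.20, "LTR": 0.15})
    msi_h_fraction: float = 5 / 21
    msi_str_ins_boost: float = 20.0
    stage_iii_fraction: float = 8 / 21
    # observation model
    mean_depth: float = 20.0
    breakpoint_jitter_sd: float = 100.0
    p_support_germline: float = 0.5
    tumor_purity: float = 1.0  # somatic support prob = purity * germline p
    fp_rate: float = 0.02  # expected false calls per emitted true call
    fn_rate_tumor: float = 0.05
    fn_rate_normal: float = 0.0
    # event-size model (bp)
    span_len_range: tuple[int, int] = (3_000, 300_000)
    ins_len_range: tuple[int, int] = (60, 2_000)
    str_ins_len_range: tuple[int, int] = (60, 600)

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate_tumor", "fn_rate_normal",
                     "msi_h_fraction", "ins_str_fraction",
                     "p_support_germline", "tumor_purity"):
            v = getattr(self, name)
            if not 0 <= v <= 1 and name not in ("tumor_purity",):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.breakpoint_jitter_sd < 0:
            raise ValueError("breakpoint_jitter_sd must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass(frozen=True)
class StrRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    motif: str
    # characteristic somatic expansion size of this locus (bp); patient
    # draws scatter around it, so expansions of one region across
    # patients merge into recurrent clusters
    expansion_len: int = 200


@dataclass
class ReferenceBundle:
    """Reference sequence plus every annotation the pipeline consumes."""

    config: SimConfig
    sequences: dict[str, str]
    str_regions: list[StrRegion]
    region_bed: list[tuple[str, int, int, str]]  # 0-based half-open + class
    library: RepeatLibrary
    me_copies: list[tuple[str, int, int, str, str]]  # chrom, start, end, class, name
    genes: list[GeneModel]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def region_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for chrom, s0, e0, cls in self.region_bed:
            trees.setdefault(chrom, IntervalTree()).addi(
                s0 + 1, e0 + 1, svio.REGION_CLASSES[cls])
        return trees


@dataclass(frozen=True)
class TruthEvent:
    event_id: str
    patient_id: str
    origin: str  # "germline" | "somatic"
    prototype: SVRecord
    repeat_class: RepeatClass


@dataclass
class SimTruth:
    """Ground-truth ledger: events plus the emitted-call provenance map
    (``call_map[sample_id][record_id]`` is an event id or None for a
    false positive)."""

    events: list[TruthEvent]
    call_map: dict[str, dict[str, Optional[str]]]

    def somatic_events(self, patient_id: str) -> list[TruthEvent]:
        return [e for e in self.events
                if e.patient_id == patient_id and e.origin == "somatic"]


@dataclass
class CohortSim:
    config: SimConfig
    reference: ReferenceBundle
    metas: list[SampleMeta]
    callsets: dict[str, Callset]
    truth: SimTruth


# ---------------------------------------------------------------------------
# Reference simulation

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _place(rng: np.random.Generator, occupied: IntervalTree,
           chrom_len: int, size: int, margin: int = 10_000,
           tries: int = 200) -> int:
    """Rejection-sample a 1-based start for a feature of ``size`` bp."""
    for _ in range(tries):
        start = int(rng.integers(margin, chrom_len - margin - size))
        if not occupied.overlap(start, start + size):
            occupied.addi(start, start + size)
            return start
    raise ValueError(
        f"genome too small to place a {size} bp feature; increase "
        f"chrom_length above {chrom_len}")


def simulate_reference(config: SimConfig) -> ReferenceBundle:
    """Generate the reference bundle: sequences with planted STR arrays
    and mobile-element copies, the repeat-region BED, the consensus
    library and multi-exon gene models. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    required = (config.str_region_count * 600
                + sum(config.mobile_element_copies.values()) * 3000
                + 100_000)
    if config.n_chromosomes * config.chrom_length < 2 * required:
        raise ValueError(
            f"genome too small for requested repeat content; need at "
            f"least {2 * required} bp total")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {c: bytearray(_random_seq(rng, config.chrom_length), "ascii")
            for c in chroms}
    occupied = {c: IntervalTree() for c in chroms}

    # consensus library: sizes echo L1 (~6 kbp, shortened), Alu (~300 bp)
    # and an LTR element (~600 bp)
    lib_sizes = {"LINE": 2500, "SINE": 300, "LTR": 600}
    entries = []
    for cls, size in lib_sizes.items():
        entries.append(RepeatEntry(
            name=f"{cls}1_synthetic", repeat_class=RepeatClass(cls),
            consensus=_random_seq(rng, size)))
    library = RepeatLibrary(entries=entries)
    by_class = {e.repeat_class.value: e for e in library}

    str_regions: list[StrRegion] = []
    region_bed: list[tuple[str, int, int, str]] = []
    lo, hi = config.str_motif_len_range
    for _ in range(config.str_region_count):
        chrom = chroms[int(rng.integers(len(chroms)))]
        motif = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        copies = int(rng.integers(*config.str_copies_range))
        array = (motif * copies)
        start = _place(rng, occupied[chrom], config.chrom_length, len(array))
        seqs[chrom][start - 1:start - 1 + len(array)] = array.encode()
        expansion = int(rng.integers(*config.str_ins_len_range))
        str_regions.append(StrRegion(chrom, start, start + len(array) - 1,
                                     motif, expansion))
        region_bed.append((chrom, start - 1, start - 1 + len(array), "STR"))

    me_copies: list[tuple[str, int, int, str, str]] = []
    for cls, n_copies in config.mobile_element_copies.items():
        entry = by_class[cls]
        for _ in range(n_copies):
            chrom = chroms[int(rng.integers(len(chroms)))]
            # 3'-anchored fragment: retrotransposition truncates the 5' end
            frag_len = int(rng.integers(max(80, len(entry.consensus) // 3),
                                        len(entry.consensus) + 1))
            frag = entry.consensus[-frag_len:]
            start = _place(rng, occupied[chrom], config.chrom_length,
                           len(frag))
            seqs[chrom][start - 1:start - 1 + len(frag)] = frag.encode()
            me_copies.append((chrom, start, start + len(frag) - 1, cls,
                              entry.name))

    for cls in ("Segdup", "Satellite", "Low_complexity"):
        for _ in range(config.other_region_count):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = int(rng.integers(2_000, 10_000))
            start = _place(rng, occupied[chrom], config.chrom_length, size)
            region_bed.append((chrom, start - 1, start - 1 + size, cls))

    genes: list[GeneModel] = []
    for chrom in chroms:
        slot = config.chrom_length // (config.genes_per_chromosome + 1)
        for gi in range(config.genes_per_chromosome):
            n_exons = int(rng.integers(4, 11))
            exon_lens = rng.integers(150, 401, n_exons)
            intron_lens = rng.integers(1_000, 5_001, n_exons - 1)
            start = slot * gi + int(rng.integers(20_000, 60_000))
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                if k < n_exons - 1:
                    pos = exons[-1][1] + 1 + int(intron_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{chrom}_gene{gi + 1}"
            genes.append(GeneModel(gene_id=gene_id, gene_name=gene_id,
                                   chrom=chrom, strand=strand,
                                   exons=tuple(exons)))

    region_bed.sort()
    return ReferenceBundle(
        config=config,
        sequences={c: bytes(b).decode() for c, b in seqs.items()},
        str_regions=str_regions, region_bed=region_bed, library=library,
        me_copies=me_copies, genes=genes)


# ---------------------------------------------------------------------------
# Cohort simulation

def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _draw_events(rng: np.random.Generator, ref: ReferenceBundle,
                 patient_id: str, origin: str, counts: dict[str, int],
                 config: SimConfig, used_str_regions: set[int],
                 n_str_ins: int, event_ids: "_IdGen",
                 region_trees) -> list[TruthEvent]:
    chroms = list(ref.sequences)
    chrom_len = config.chrom_length
    events: list[TruthEvent] = []

    def rand_pos(margin: int = 20_000) -> tuple[str, int]:
        c = chroms[int(rng.integers(len(chroms)))]
        return c, int(rng.integers(margin, chrom_len - margin))

    for svtype, n in counts.items():
        if svtype == "INS":
            continue  # insertions handled below (class mixture)
        for _ in range(n):
            eid = event_ids.next(patient_id, origin)
            if svtype == "TRA":
                c1, p1 = rand_pos()
                c2 = chroms[(chroms.index(c1) + 1) % len(chroms)]
                p2 = int(rng.integers(20_000, chrom_len - 20_000))
                proto = SVRecord(record_id=eid, sample_id=patient_id,
                                 chrom=c1, pos=p1, chrom2=c2, pos2=p2,
                                 svtype="TRA", svlen=0, support=0)
                cls = RepeatClass.NONE
            else:
                length = _log_uniform(rng, *config.span_len_range)
                c, p = rand_pos(margin=length + 20_000)
                proto = SVRecord(record_id=eid, sample_id=patient_id,
                                 chrom=c, pos=p, end=p + length,
                                 svtype=svtype, svlen=length, support=0)
                cls = (svio.region_class_at(region_trees, c, p)
                       or RepeatClass.NONE)
            events.append(TruthEvent(eid, patient_id, origin, proto, cls))

    # insertion mixture: STR expansions at STR regions, mobile-element
    # fragments, and repeat-free sequence
    n_ins = counts.get("INS", 0)
    n_str = min(n_str_ins, n_ins) if origin == "germline" else n_str_ins
    forbidden = set(used_str_regions)
    available = [i for i in range(len(ref.str_regions))
                 if i not in forbidden]
    if not available and n_str > 0:
        raise ValueError("str_region_count too small for the requested "
                         "STR-insertion load")
    rng.shuffle(available)
    for k in range(n_str):
        if not available:
            # pool exhausted: reuse loci (two expansions of one region
            # in a patient merge at the cohort stage, which is fine)
            available = [i for i in range(len(ref.str_regions))
                         if i not in forbidden]
            rng.shuffle(available)
        ridx = available.pop()
        used_str_regions.add(ridx)
        region = ref.str_regions[ridx]
        motif = region.motif
        # scatter +/-10% around the locus' characteristic expansion size
        target = region.expansion_len * (1 + rng.uniform(-0.1, 0.1))
        copies = max(3, int(round(target / len(motif))))
        seq = motif * copies
        pos = int(rng.integers(region.start, region.end + 1))
        eid = event_ids.next(patient_id, origin)
        proto = SVRecord(record_id=eid, sample_id=patient_id,
                         chrom=region.chrom, pos=pos, svtype="INS",
                         svlen=len(seq), support=0, seq=seq)
        events.append(TruthEvent(eid, patient_id, origin, proto,
                                 RepeatClass.STR))

    n_other = max(0, n_ins - (n_str if origin == "germline" else 0))
    if origin == "somatic":
        n_other = n_ins  # boost adds STR events on top of the baseline mix
    me_classes = list(config.ins_mobile_fractions)
    me_probs = np.array([config.ins_mobile_fractions[c] for c in me_classes])
    p_none = 1.0 - me_probs.sum()
    by_class = {e.repeat_class.value: e for e in ref.library}
    for _ in range(n_other):
        eid = event_ids.next(patient_id, origin)
        u = rng.random()
        c, p = rand_pos()
        if u < p_none:
            seq = _random_seq(rng, _log_uniform(rng, *config.ins_len_range))
            cls = RepeatClass.NONE
        else:
            idx = int(rng.choice(len(me_classes),
                                 p=me_probs / me_probs.sum()))
            entry = by_class[me_classes[idx]]
            frag_len = int(rng.integers(max(80, len(entry.consensus) // 3),
                                        len(entry.consensus) + 1))
            seq = entry.consensus[-frag_len:]
            if rng.random() < 0.5:
                comp = seq.translate(str.maketrans("ACGT", "TGCA"))
                seq = comp[::-1]
            cls = entry.repeat_class
        proto = SVRecord(record_id=eid, sample_id=patient_id, chrom=c,
                         pos=p, svtype="INS", svlen=len(seq), support=0,
                         seq=seq)
        events.append(TruthEvent(eid, patient_id, origin, proto, cls))
    return events


class _IdGen:
    def __init__(self):
        self.counter = 0

    def next(self, patient_id: str, origin: str) -> str:
        self.counter += 1
        return f"{patient_id}_{origin[0]}{self.counter:05d}"


def _emit_call(rng: np.random.Generator, event: TruthEvent,
               sample: SampleMeta, p_support: float,
               config: SimConfig, counter: int) -> Optional[SVRecord]:
    """One observed call from a truth event: jittered breakpoints and
    binomial support; calls with <2 reads vanish (caller floor)."""
    proto = event.prototype
    sd = config.breakpoint_jitter_sd
    depth = max(1, int(round(sample.mean_depth)))
    support = int(rng.binomial(depth, p_support))
    if support < 2:
        return None
    chrom_len = config.chrom_length

    def jitter(x: int) -> int:
        if sd == 0:
            return x
        return int(min(max(1, round(x + rng.normal(0, sd))), chrom_len))

    rid = f"{sample.sample_id}_call{counter:05d}"
    if proto.svtype == "TRA":
        return proto.copy(record_id=rid, sample_id=sample.sample_id,
                          pos=jitter(proto.pos), pos2=jitter(proto.pos2),
                          support=support)
    if proto.svtype == "INS":
        return proto.copy(record_id=rid, sample_id=sample.sample_id,
                          pos=jitter(proto.pos), end=None, support=support)
    pos, end = jitter(proto.pos), jitter(proto.end)
    if end - pos < 50:  # keep the call ingest-valid under extreme jitter
        pos, end = proto.pos, proto.end
    return proto.copy(record_id=rid, sample_id=sample.sample_id, pos=pos,
                      end=end, svlen=end - pos, support=support)


def _false_positive(rng: np.random.Generator, sample: SampleMeta,
                    config: SimConfig, chroms: list[str],
                    counter: int) -> SVRecord:
    svtype = ["DEL", "INS", "DUP", "INV", "TRA"][int(rng.integers(5))]
    chrom_len = config.chrom_length
    support = 2 + int(rng.poisson(1.0))
    rid = f"{sample.sample_id}_fp{counter:05d}"
    c = chroms[int(rng.integers(len(chroms)))]
    pos = int(rng.integers(20_000, chrom_len - 400_000))
    if svtype == "TRA":
        c2 = chroms[(chroms.index(c) + 1) % len(chroms)]
        return SVRecord(record_id=rid, sample_id=sample.sample_id, chrom=c,
                        pos=pos, chrom2=c2,
                        pos2=int(rng.integers(20_000, chrom_len - 20_000)),
                        svtype="TRA", svlen=0, support=support)
    if svtype == "INS":
        seq = _random_seq(rng, _log_uniform(rng, *config.ins_len_range))
        return SVRecord(record_id=rid, sample_id=sample.sample_id, chrom=c,
                        pos=pos, svtype="INS", svlen=len(seq),
                        support=support, seq=seq)
    length = _log_uniform(rng, *config.span_len_range)
    return SVRecord(record_id=rid, sample_id=sample.sample_id, chrom=c,
                    pos=pos, end=pos + length, svtype=svtype, svlen=length,
                    support=support)


def simulate_cohort(reference: ReferenceBundle,
                    config: Optional[SimConfig] = None) -> CohortSim:
    """Simulate the paired cohort on a reference bundle.

    Germline events are emitted in both members of a pair (independent
    jitter and support draws); somatic events in the tumor only. MSI-H
    tumors receive ``msi_str_ins_boost`` times the baseline somatic
    STR-insertion mean. Per-patient event counts are Poisson around the
    configured means. Deterministic per seed.
    """
    config = config or reference.config
    rng = np.random.default_rng(config.seed + 1)
    chroms = list(reference.sequences)
    region_trees = reference.region_trees()

    n_msi = int(round(config.msi_h_fraction * config.n_patients))
    msi_patients = set(rng.choice(config.n_patients, size=n_msi,
                                  replace=False).tolist())
    metas: list[SampleMeta] = []
    events: list[TruthEvent] = []
    callsets: dict[str, Callset] = {}
    call_map: dict[str, dict[str, Optional[str]]] = {}
    event_ids = _IdGen()

    for pi in range(config.n_patients):
        patient = f"P{pi + 1:02d}"
        msi = "MSI-H" if pi in msi_patients else "MSS"
        stage = "III" if rng.random() < config.stage_iii_fraction else "II"
        tumor = SampleMeta(sample_id=f"{patient}-T", patient_id=patient,
                           role="tumor", mean_depth=config.mean_depth,
                           msi_status=msi, stage=stage)
        normal = SampleMeta(sample_id=f"{patient}-N", patient_id=patient,
                            role="normal", mean_depth=config.mean_depth,
                            msi_status=msi, stage=stage)
        metas.extend([tumor, normal])

        used_str: set[int] = set()
        germ_counts = {t: int(rng.poisson(m))
                       for t, m in config.germline_counts.items()}
        germ_str = int(round(germ_counts.get("INS", 0)
                             * config.ins_str_fraction))
        germline = _draw_events(rng, reference, patient, "germline",
                                germ_counts, config, used_str, germ_str,
                                event_ids, region_trees)
        som_counts = {t: int(rng.poisson(m))
                      for t, m in config.somatic_counts.items()}
        str_mean = config.somatic_counts.get("INS", 0) * config.ins_str_fraction
        if msi == "MSI-H":
            str_mean *= config.msi_str_ins_boost
        som_str = int(rng.poisson(str_mean))
        som_counts["INS"] = int(rng.poisson(
            config.somatic_counts.get("INS", 0)
            * (1 - config.ins_str_fraction)))
        somatic = _draw_events(rng, reference, patient, "somatic",
                               som_counts, config, used_str, som_str,
                               event_ids, region_trees)
        # somatic loci are kept distinct from the patient's germline loci:
        # a somatic change on top of a germline call at the same locus is
        # not representable at callset level, so such draws are discarded
        germ_index = _MatchIndex([e.prototype for e in germline])
        somatic = [ev for ev in somatic
                   if not any(_breakpoint_distance(ev.prototype, g) <= 2_000
                              for g in germ_index.candidates(
                                  ev.prototype, 2_000))]
        events.extend(germline)
        events.extend(somatic)

        for sample, pool, fn_rate in (
                (tumor, germline + somatic, config.fn_rate_tumor),
                (normal, germline, config.fn_rate_normal)):
            records: list[SVRecord] = []
            mapping: dict[str, Optional[str]] = {}
            counter = 0
            for ev in pool:
                if rng.random() < fn_rate:
                    continue
                p = config.p_support_germline
                if ev.origin == "somatic":
                    p = config.p_support_germline * config.tumor_purity
                counter += 1
                call = _emit_call(rng, ev, sample, p, config, counter)
                if call is not None:
                    records.append(call)
                    mapping[call.record_id] = ev.event_id
            n_fp = int(rng.poisson(config.fp_rate * max(1, len(records))))
            for k in range(n_fp):
                fp = _false_positive(rng, sample, config, chroms, k + 1)
                records.append(fp)
                mapping[fp.record_id] = None
            callsets[sample.sample_id] = Callset(sample=sample,
                                                 records=records)
            call_map[sample.sample_id] = mapping

    return CohortSim(config=config, reference=reference, metas=metas,
                     callsets=callsets,
                     truth=SimTruth(events=events, call_map=call_map))


# ---------------------------------------------------------------------------
# Writers

def write_reference_bundle(ref: ReferenceBundle, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    svio.write_fasta(ref.sequences, os.path.join(outdir, "reference.fa"))
    with open(os.path.join(outdir, "repeats.bed"), "w") as fh:
        for chrom, s0, e0, cls in ref.region_bed:
            fh.write(f"{chrom}\t{s0}\t{e0}\t{cls}\n")
    svio.write_repeat_library(ref.library,
                              os.path.join(outdir, "repeat_library.fa"))
    with open(os.path.join(outdir, "genes.bed"), "w") as fh:
        for g in ref.genes:
            start0 = g.start - 1
            sizes = ",".join(str(e - s + 1) for s, e in g.exons)
            starts = ",".join(str(s - 1 - start0) for s, _ in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, start0, g.end, g.gene_id, 0, g.strand, start0,
                g.end, "0,0,0", g.n_exons, sizes, starts])) + "\n")


def write_cohort(sim: CohortSim, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    svio.write_metadata(sim.metas, os.path.join(outdir, "metadata.tsv"))
    lengths = sim.reference.contig_lengths
    for sample_id, callset in sim.callsets.items():
        svio.write_sv_vcf(callset, os.path.join(outdir, f"{sample_id}.vcf"),
                          contig_lengths=lengths)
    rows = []
    for ev in sim.truth.events:
        p = ev.prototype
        rows.append({
            "event_id": ev.event_id, "patient_id": ev.patient_id,
            "origin": ev.origin, "svtype": p.svtype, "chrom": p.chrom,
            "pos": p.pos, "end": p.end if p.end is not None else "",
            "chrom2": p.chrom2 or "", "pos2": p.pos2 or "",
            "svlen": p.svlen, "repeat_class": ev.repeat_class.value,
        })
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth_events.tsv"),
                              sep="\t", index=False)
    rows = []
    for sample_id, mapping in sim.truth.call_map.items():
        for rid, eid in mapping.items():
            rows.append({"sample_id": sample_id, "record_id": rid,
                         "event_id": eid if eid is not None else "FP"})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth_calls.tsv"),
                              sep="\t", index=False)
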