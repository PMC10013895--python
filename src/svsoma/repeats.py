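"""Repeat-content classification of insertion/deletion sequences.

Two lightweight detectors replace genome-annotation suites:

* a tandem-repeat detector that scans motif periods 1-100 via
  self-comparison of the sequence at each candidate lag, tolerating a
  bounded divergence within the array (default 10%). A call is made
  when the best array reaches 3 copies and covers 80% of the sequence;
  motifs of <=6 bp are microsatellites (STR), longer ones generic
  tandem repeats.
* a mobile-element classifier that locally aligns the variant sequence
  (both strands) against a small consensus library (LINE/SINE/LTR) and
  assigns the best class when the alignment covers >=50% of the
  sequence at >=70% identity.

Loci without sequence fall back to a repeat-region track (BED) carrying
Segdup/Satellite/Low_complexity/STR intervals. All thresholds are
arguments with the defaults above.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io import region_class_at
from .model import (MergedSV, RepeatClass, RepeatLibrary, SVRecord,
                    TandemRepeatCall)

_VALID_BASES = frozenset("ACGTN")

#: integer scaling used to keep the divergence bound exact
_DIV_SCALE = 1000


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation of a motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _longest_tolerant_window(z: np.ndarray, max_div_scaled: int
                             ) -> tuple[int, int]:
    """Longest window [l, r) of the 0/1 array ``z`` whose mismatch count
    satisfies ``sum(z) * SCALE <= max_div_scaled * (r - l)``.

    Solved exactly as the longest subarray with non-positive sum of the
    integer weights ``SCALE*z - max_div_scaled`` using prefix strict
    maxima and a binary search (no floating point).
    """
    w = z.astype(np.int64) * _DIV_SCALE - max_div_scaled
    prefix = np.concatenate(([0], np.cumsum(w)))
    run_max = np.maximum.accumulate(prefix)
    strict = np.empty(len(prefix), dtype=bool)
    strict[0] = True
    strict[1:] = prefix[1:] > run_max[:-1]
    cand_idx = np.nonzero(strict)[0]
    cand_val = prefix[cand_idx]  # increasing
    # for each right end r: leftmost candidate l with prefix[l] >= prefix[r]
    pos = np.searchsorted(cand_val, prefix, side="left")
    valid = pos < len(cand_idx)
    left = np.where(valid, cand_idx[np.minimum(pos, len(cand_idx) - 1)],
                    np.arange(len(prefix)))
    lengths = np.arange(len(prefix)) - left
    r = int(np.argmax(lengths))
    return int(left[r]), r


def detect_tandem_repeat(seq: str, max_period: int = 100,
                         min_copies: float = 3.0,
                         min_coverage: float = 0.8,
                         max_divergence: float = 0.1,
                         ) -> Optional[TandemRepeatCall]:
    """Detect the dominant tandem-repeat array in a variant sequence.

    Periods are tested shortest-first; the winning period is the
    shortest one whose (perfect or tolerantly degenerate) array covers
    the most bases. Returns ``None`` unless the array reaches
    ``min_copies`` copies and covers ``min_coverage`` of the sequence.
    The motif is the per-phase consensus of the array reported in its
    canonical (lexicographically smallest) rotation.
    """
    seq = seq.upper()
    if len(seq) < 50:
        raise ValueError("tandem-repeat detection requires >= 50 bp")
    if not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    max_div_scaled = int(round(max_divergence * _DIV_SCALE))
    p_limit = min(max_period, int(n // min_copies))
    best = None  # (covered, period, array_start)
    for p in range(1, p_limit + 1):
        z = (s[p:] != s[:-p]).astype(np.int64)
        l, r = _longest_tolerant_window(z, max_div_scaled)
        if r <= l:
            continue
        covered = (r - l) + p
        if best is None or covered > best[0]:
            best = (covered, p, l)
    if best is None:
        return None
    covered, period, start = best
    copy_number = covered / period
    covered_fraction = covered / n
    if copy_number < min_copies or covered_fraction < min_coverage:
        return None
    # per-phase consensus over the array region, anchored at its start
    region = seq[start:start + covered]
    motif_chars = []
    for phase in range(period):
        votes = Counter(region[phase::period])
        top = max(votes.values())
        motif_chars.append(min(c for c, v in votes.items() if v == top))
    motif = canonical_rotation("".join(motif_chars))
    return TandemRepeatCall(motif=motif, copy_number=copy_number,
                            covered_fraction=covered_fraction)


def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(mode="local", match_score=2,
                                 mismatch_score=-3, open_gap_score=-5,
                                 extend_gap_score=-2)


def classify_mobile_element(seq: str, library: RepeatLibrary,
                            min_query_coverage: float = 0.5,
                            min_identity: float = 0.7,
                            ) -> Optional[tuple[RepeatClass, str]]:
    """Assign a mobile-element class by local alignment to the library.

    Both strands of ``seq`` are aligned against every consensus; the
    best-scoring entry wins if its alignment covers at least
    ``min_query_coverage`` of the sequence at ``min_identity``. Ties go
    to higher coverage, then library order. Returns ``None`` when no
    entry qualifies.
    """
    seq = seq.upper()
    if len(seq) < 50:
        raise ValueError("mobile-element classification requires >= 50 bp")
    if len(library) == 0:
        raise ValueError("empty repeat library")
    aligner = _make_aligner()
    queries = (seq, str(Seq(seq).reverse_complement()))
    best = None  # (score, coverage, -order, class, name)
    for order, entry in enumerate(library):
        for query in queries:
            alignments = aligner.align(entry.consensus, query)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            counts = aln.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns == 0:
                continue
            identity = counts.identities / columns
            q_blocks = aln.aligned[1]
            coverage = sum(int(e) - int(s) for s, e in q_blocks) / len(seq)
            if coverage < min_query_coverage or identity < min_identity:
                continue
            key = (aln.score, coverage, -order)
            if best is None or key > best[:3]:
                best = (aln.score, coverage, -order,
                        entry.repeat_class, entry.name)
    if best is None:
        return None
    return best[3], best[4]


def classify_record(sv: SVRecord, library: RepeatLibrary,
                    region_track: Optional[dict[str, IntervalTree]] = None,
                    **detector_kwargs) -> RepeatClass:
    """Classify a deletion or insertion by repeat content.

    Precedence: tandem repeat detected in the variant sequence, then
    mobile element by library alignment, then the repeat-region class
    at the SV locus, then ``None``. Records lacking a usable sequence
    fall through to the region track and come back ``Unclassifiable``
    when no track covers the locus.
    """
    if sv.svtype not in ("DEL", "INS"):
        raise ValueError(
            f"{sv.record_id}: repeat classification applies to DEL/INS, "
            f"not {sv.svtype}")
    has_seq = sv.seq is not None and len(sv.seq) >= 50
    if has_seq:
        tr = detect_tandem_repeat(sv.seq, **detector_kwargs)
        if tr is not None:
            return tr.repeat_class
        hit = classify_mobile_element(sv.seq, library)
        if hit is not None:
            return hit[0]
    if region_track is not None:
        region = region_class_at(region_track, sv.chrom, sv.pos)
        if region is not None:
            return region
    return RepeatClass.NONE if has_seq else RepeatClass.UNCLASSIFIABLE


def str_exclusion_split(merged: Iterable[MergedSV],
                        classes: dict[str, RepeatClass],
                        ) -> tuple[list[MergedSV], list[MergedSV]]:
    """Split the merged call set into (all clusters, clusters without
    STR insertions).

    STR-driven insertion calls dominate microsatellite-unstable tumors,
    so cohort type proportions are reported both ways. Every INS
    cluster must appear in ``classes``; anything else is a bookkeeping
    error upstream.
    """
    merged = list(merged)
    unclassified = [m.cluster_id for m in merged
                    if m.svtype == "INS" and m.cluster_id not in classes]
    if unclassified:
        raise ValueError(
            f"unclassified INS clusters: {unclassified[:5]}"
            + ("..." if len(unclassified) > 5 else ""))
    kept = [m for m in merged
            if not (m.svtype == "INS"
                    and classes[m.cluster_id] == RepeatClass.STR)]
    return merged, kept


def type_proportions(clusters: Iterable[MergedSV]) -> dict[str, float]:
    """Per-type fractions over a cluster collection (sum to 1)."""
    clusters = list(clusters)
    if not clusters:
        return {}
    counts = Counter(m.svtype for m in clusters)
    total = len(clusters)
    return {t: counts.get(t, 0) / total for t in sorted(counts)}
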