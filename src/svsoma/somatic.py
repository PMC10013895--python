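"""Somatic SV derivation from a tumor/normal callset pair.

The pipeline stage implemented here mirrors a callset-level strategy
for long-read SV calls at moderate (~20x) depth:

1. tumor calls are kept only when their read support reaches a fraction
   (default 0.3) of the sample's mean sequencing depth;
2. a tumor call is subtracted as germline when it matches any normal
   call with >=2 supporting reads. The normal side is deliberately left
   at this lenient read-support threshold and is *not* depth-filtered,
   trading normal-side precision for recall so that surviving tumor
   calls are reliably somatic.

Two calls match when they have the same type and chromosome(s), their
breakpoints lie within ``max_dist`` (default 1 kbp), spanning types
(DEL/INV/DUP) reciprocally overlap by at least 40% of the longer span,
and sized types differ in length by less than 20% of the longer length.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right

from .model import Callset, MatchParams, SVRecord


def depth_support_filter(callset: Callset,
                         params: MatchParams = MatchParams()) -> Callset:
    """Keep calls with support >= depth_support_frac x mean sample depth.

    The threshold is compared directly (no rounding): at depth 20 and
    fraction 0.3, support 6 passes and support 5 does not.
    """
    threshold = params.depth_support_frac * callset.sample.mean_depth
    kept = [r for r in callset if r.support >= threshold]
    return Callset(sample=callset.sample, records=kept,
                   somatic=callset.somatic)


def _breakpoint_distance(a: SVRecord, b: SVRecord) -> int:
    if a.svtype == "INS":
        return abs(a.pos - b.pos)
    if a.svtype == "TRA":
        return max(abs(a.pos - b.pos), abs(a.pos2 - b.pos2))
    return max(abs(a.pos - b.pos), abs(a.end - b.end))


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """Shared span divided by the longer span (symmetric, in [0, 1])."""
    overlap = min(a.end, b.end) - max(a.pos, b.pos) + 1
    if overlap <= 0:
        return 0.0
    return overlap / max(a.span, b.span)


def sv_match(a: SVRecord, b: SVRecord,
             params: MatchParams = MatchParams()) -> bool:
    """True iff two calls describe the same structural variant.

    Symmetric in its arguments and reflexive on any valid record. The
    reciprocal-overlap criterion applies to DEL/INV/DUP only; the
    length criterion to every sized type (TRA carries no length and is
    matched on its two junction ends alone).
    """
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    if a.svtype == "TRA" and a.chrom2 != b.chrom2:
        return False
    if _breakpoint_distance(a, b) > params.max_dist:
        return False
    if a.svtype in ("DEL", "DUP", "INV"):
        if reciprocal_overlap(a, b) < params.min_reciprocal_overlap:
            return False
    if a.svtype != "TRA":
        longer = max(a.svlen, b.svlen)
        if longer > 0:
            if abs(a.svlen - b.svlen) / longer >= params.max_len_diff_frac:
                return False
    return True


class _MatchIndex:
    """Positional index over one callset for window-limited matching.

    Only pairs whose first breakpoints lie within ``max_dist`` can
    match, so candidates are found by bisecting a per-(svtype, chrom)
    sorted position list.
    """

    def __init__(self, records, min_support: int = 0):
        self._by_key: dict[tuple, list[tuple[int, SVRecord]]] = {}
        for r in records:
            if r.support < min_support:
                continue
            key = (r.svtype, r.chrom)
            self._by_key.setdefault(key, []).append((r.pos, r))
        for entries in self._by_key.values():
            entries.sort(key=lambda t: t[0])

    def candidates(self, r: SVRecord, max_dist: int):
        entries = self._by_key.get((r.svtype, r.chrom), [])
        positions = [p for p, _ in entries]
        lo = bisect_left(positions, r.pos - max_dist)
        hi = bisect_right(positions, r.pos + max_dist)
        return [rec for _, rec in entries[lo:hi]]


def somatic_subtract(tumor: Callset, normal: Callset,
                     params: MatchParams = MatchParams()) -> Callset:
    """Derive somatic calls: depth-filter the tumor, then remove every
    call matching a normal call with support >= min_normal_support.

    The normal callset is used as-is apart from the read-support floor;
    depth filtering it would lower normal recall and let germline calls
    masquerade as somatic.
    """
    if tumor.sample.patient_id != normal.sample.patient_id:
        raise ValueError(
            f"tumor {tumor.sample.sample_id} (patient "
            f"{tumor.sample.patient_id}) and normal "
            f"{normal.sample.sample_id} (patient "
            f"{normal.sample.patient_id}) are not a pair")
    high_conf = depth_support_filter(tumor, params)
    index = _MatchIndex(normal.records, min_support=params.min_normal_support)
    somatic = [r for r in high_conf
               if not any(sv_match(r, n, params)
                          for n in index.candidates(r, params.max_dist))]
    return Callset(sample=tumor.sample, records=somatic, somatic=True)
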