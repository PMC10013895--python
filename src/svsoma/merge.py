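"""Cross-sample merging of somatic callsets and recurrence statistics.

Somatic calls from all patients are clustered with the same matching
predicate used for tumor-normal subtraction. The default linkage is
single (clusters are connected components of the pairwise match graph),
the convention of multi-sample SV merging tools; complete linkage is
available for stricter clustering. Recurrence counts distinct patients
per cluster, so fragmented calls within one tumor count once.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Literal

import pandas as pd

from .model import Callset, MatchParams, MergedSV, SVRecord
from .somatic import _MatchIndex, sv_match


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _patient_of(record: SVRecord,
                sample_to_patient: dict[str, str]) -> str:
    return sample_to_patient.get(record.sample_id, record.sample_id)


def merge_cohort(somatic_callsets: Iterable[Callset],
                 params: MatchParams = MatchParams(),
                 linkage: Literal["single", "complete"] = "single",
                 ) -> list[MergedSV]:
    """Merge per-patient somatic callsets into a nonredundant call set.

    Every input record lands in exactly one cluster. The representative
    is the member with maximal read support (ties broken by coordinate,
    then sample id) and clusters are returned ordered by representative
    coordinate. Cluster membership is independent of input order.
    """
    callsets = list(somatic_callsets)
    if not callsets:
        raise ValueError("merge_cohort requires at least one callset")
    sample_to_patient = {c.sample.sample_id: c.sample.patient_id
                         for c in callsets}
    records = [r for c in callsets for r in c]
    # canonical record order makes clustering independent of input order
    records.sort(key=lambda r: (r.chrom, r.pos, r.svtype, r.sample_id,
                                r.record_id))
    if not records:
        return []

    groups: list[list[SVRecord]]
    if linkage == "single":
        uf = _UnionFind(len(records))
        index_of = {id(r): i for i, r in enumerate(records)}
        pos_index = _MatchIndex(records)
        for i, r in enumerate(records):
            for cand in pos_index.candidates(r, params.max_dist):
                j = index_of[id(cand)]
                if j <= i:
                    continue
                if sv_match(r, cand, params):
                    uf.union(i, j)
        by_root: dict[int, list[SVRecord]] = defaultdict(list)
        for i, r in enumerate(records):
            by_root[uf.find(i)].append(r)
        groups = list(by_root.values())
    elif linkage == "complete":
        groups = []
        pos_index = _MatchIndex(records)
        assigned: dict[int, int] = {}
        for i, r in enumerate(records):
            placed = False
            candidate_groups = sorted(
                {assigned[id(c)] for c in
                 pos_index.candidates(r, params.max_dist)
                 if id(c) in assigned})
            for gi in candidate_groups:
                if all(sv_match(r, m, params) for m in groups[gi]):
                    groups[gi].append(r)
                    assigned[id(r)] = gi
                    placed = True
                    break
            if not placed:
                assigned[id(r)] = len(groups)
                groups.append([r])
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    merged: list[MergedSV] = []
    for members in groups:
        # representative: maximal support, ties by smallest coordinate
        best_support = max(m.support for m in members)
        rep = min((m for m in members if m.support == best_support),
                  key=lambda r: (r.chrom, r.pos, r.sample_id, r.record_id))
        patients = {_patient_of(m, sample_to_patient) for m in members}
        merged.append(MergedSV(
            cluster_id="", members=sorted(
                members, key=lambda r: (r.sample_id, r.record_id)),
            representative=rep, recurrence=len(patients),
            svtype=rep.svtype))
    merged.sort(key=lambda m: (m.representative.chrom, m.representative.pos,
                               m.svtype, m.representative.record_id))
    for i, m in enumerate(merged):
        m.cluster_id = f"cluster_{i:05d}"
    return merged


def recurrence_table(merged: Iterable[MergedSV]) -> pd.DataFrame:
    """Tabulate cluster counts by SV type and recurrence level.

    Returns a long-format table with columns ``svtype``, ``recurrence``
    and ``n_clusters``; level counts partition the clusters of each
    type. Companion columns give, per type, the fraction of clusters
    seen in >=2 patients and the singleton fraction.
    """
    merged = list(merged)
    counts: Counter[tuple[str, int]] = Counter(
        (m.svtype, m.recurrence) for m in merged)
    rows = []
    type_totals: Counter[str] = Counter(m.svtype for m in merged)
    for (svtype, level), n in sorted(counts.items()):
        total = type_totals[svtype]
        recurrent = sum(v for (t, l), v in counts.items()
                        if t == svtype and l >= 2)
        rows.append({
            "svtype": svtype, "recurrence": level, "n_clusters": n,
            "type_total": total,
            "frac_recurrent": recurrent / total,
            "frac_singleton": counts.get((svtype, 1), 0) / total,
        })
    return pd.DataFrame(
        rows, columns=["svtype", "recurrence", "n_clusters", "type_total",
                       "frac_recurrent", "frac_singleton"])


def fraction_recurrent(merged: Iterable[MergedSV]) -> float:
    """Fraction of clusters detected in at least two patients."""
    merged = list(merged)
    if not merged:
        return 0.0
    return sum(m.recurrence >= 2 for m in merged) / len(merged)
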