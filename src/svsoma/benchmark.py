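"""Recovery metrics of the somatic pipeline against simulator truth.

A predicted somatic call counts as correct when it matches a somatic
truth event of the same patient under the standard matching predicate
(type, breakpoint distance, reciprocal overlap, length ratio).
Precision is call-level (fraction of calls hitting some event); recall
is event-level (fraction of events hit by some call), so fragmented
duplicate calls neither inflate recall nor escape the precision
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import Callset, MatchParams
from .simulate import SimTruth
from .somatic import _MatchIndex, sv_match


@dataclass(frozen=True)
class RecoveryMetrics:
    n_calls: int
    n_calls_matched: int
    n_events: int
    n_events_matched: int

    @property
    def precision(self) -> float:
        return self.n_calls_matched / self.n_calls if self.n_calls else 1.0

    @property
    def recall(self) -> float:
        return (self.n_events_matched / self.n_events
                if self.n_events else 1.0)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def evaluate_somatic(somatic_callsets: Iterable[Callset], truth: SimTruth,
                     params: MatchParams = MatchParams()) -> RecoveryMetrics:
    """Score per-patient somatic callsets against the truth ledger."""
    n_calls = n_calls_matched = n_events = n_events_matched = 0
    for callset in somatic_callsets:
        patient = callset.sample.patient_id
        prototypes = [e.prototype for e in truth.somatic_events(patient)]
        index = _MatchIndex(prototypes)
        matched_truth: set[str] = set()
        for call in callset:
            hits = [p for p in index.candidates(call, params.max_dist)
                    if sv_match(call, p, params)]
            n_calls += 1
            if hits:
                n_calls_matched += 1
                matched_truth.update(h.record_id for h in hits)
        n_events += len(prototypes)
        n_events_matched += len(matched_truth)
    return RecoveryMetrics(n_calls=n_calls, n_calls_matched=n_calls_matched,
                           n_events=n_events,
                           n_events_matched=n_events_matched)
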