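"""Precision/recall of called sites against planted ground truth.

A call matches a truth site when the gap between the call interval and
the truth 5-mer interval is at most ``window`` nt (0 for touching or
overlapping intervals).  Matching is many-to-many: a chained cluster
spanning two closely spaced truth sites recovers both, and both
directions count it as correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .models import ModSite
from .simulate import TruthSite


def _interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, lo - hi)


@dataclass(frozen=True)
class BenchmarkResult:
    n_calls: int
    n_truth: int
    n_calls_matched: int
    n_truth_recovered: int

    @property
    def precision(self) -> float:
        return self.n_calls_matched / self.n_calls if self.n_calls else float("nan")

    @property
    def recall(self) -> float:
        return (
            self.n_truth_recovered / self.n_truth if self.n_truth else float("nan")
        )


def evaluate_calls(
    sites: Sequence[ModSite],
    truth: Sequence[TruthSite],
    window: int = 10,
) -> BenchmarkResult:
    truth_by_tx: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        truth_by_tx.setdefault(t.transcript_id, []).append(
            (t.position, t.position + 5)
        )
    calls_by_tx: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        calls_by_tx.setdefault(s.transcript_id, []).append((s.start, s.end))

    n_calls_matched = sum(
        any(
            _interval_gap(c, t) <= window
            for t in truth_by_tx.get(tx, [])
        )
        for tx, calls in calls_by_tx.items()
        for c in calls
    )
    n_truth_recovered = sum(
        any(
            _interval_gap(t, c) <= window
            for c in calls_by_tx.get(tx, [])
        )
        for tx, truths in truth_by_tx.items()
        for t in truths
    )
    return BenchmarkResult(
        n_calls=len(sites),
        n_truth=len(truth),
        n_calls_matched=int(n_calls_matched),
        n_truth_recovered=int(n_truth_recovered),
    )
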