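"""Piecewise-constant genomic interval index (step vector).

Each reference sequence gets one :class:`StepVector`: an ordered partition of
[0, L) into steps, each carrying the immutable set of (feature, rule)
candidates whose Stage-2 match window covers every position of the step.
Queries return all candidates overlapping an interval by at least one
nucleotide in O(steps overlapped + log steps).

Strand is deliberately not an index dimension: strand compatibility is a
Stage-3 rule check, not an index miss.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Hashable, Iterable, Iterator, Mapping

logger = logging.getLogger("srnacount")


@dataclass(frozen=True)
class CandidateHit:
    """A (feature, rule) pair that survived Stage 1, with its match window.

    ``match_window`` is the rule-shifted, clamped genomic window used for
    indexing; the raw feature interval and strand are carried along for the
    Stage-2 positional tests.
    """

    feature_id: str
    rule_index: int
    match_window: tuple[int, int]  # 0-based half-open
    feature_strand: str
    ref_name: str
    feature_start: int
    feature_end: int

    def __post_init__(self) -> None:
        if self.match_window[1] <= self.match_window[0]:
            raise ValueError(
                f"empty match window for {self.feature_id} rule {self.rule_index}")


class StepVector:
    """Canonical piecewise-constant map position -> frozenset of candidates.

    Steps tile [0, L) exactly; adjacent steps never carry identical sets.
    """

    def __init__(self, length: int, starts: list[int], values: list[frozenset]):
        self.length = length
        self._starts = starts
        self._values = values

    @classmethod
    def build(cls, length: int,
              windows: Iterable[tuple[int, int, Hashable]]) -> "StepVector":
        """Build from (start, end, candidate) windows via a boundary sweep.

        The sweep makes the result insertion-order independent by
        construction; equal adjacent steps are merged to canonical form.
        """
        if length <= 0:
            raise ValueError("axis length must be positive")
        events: dict[int, list[tuple[Hashable, int]]] = {}
        bounds = {0, length}
        clamped_note = False
        items = []
        for start, end, cand in windows:
            s, e = max(0, start), min(length, end)
            if (s, e) != (start, end) and not clamped_note:
                logger.info("candidate window [%d,%d) clamped to axis [0,%d)",
                            start, end, length)
                clamped_note = True
            if e <= s:
                continue
            items.append((s, e, cand))
            bounds.add(s)
            bounds.add(e)
        ordered = sorted(bounds)
        # active set per elementary interval
        starts: list[int] = []
        values: list[frozenset] = []
        open_at: dict[int, list] = {}
        close_at: dict[int, list] = {}
        for s, e, cand in items:
            open_at.setdefault(s, []).append(cand)
            close_at.setdefault(e, []).append(cand)
        active: dict[Hashable, int] = {}
        for b in ordered[:-1]:
            for cand in close_at.get(b, ()):  # close before open at a boundary
                active[cand] -= 1
                if not active[cand]:
                    del active[cand]
            for cand in open_at.get(b, ()):
                active[cand] = active.get(cand, 0) + 1
            value = frozenset(active)
            if values and values[-1] == value:
                continue  # canonical merge
            starts.append(b)
            values.append(value)
        if not starts:
            starts, values = [0], [frozenset()]
        return cls(length, starts, values)

    def steps(self) -> Iterator[tuple[int, int, frozenset]]:
        """Yield (start, end, candidate set) over the whole axis."""
        for i, s in enumerate(self._starts):
            e = self._starts[i + 1] if i + 1 < len(self._starts) else self.length
            yield s, e, self._values[i]

    def value_at(self, pos: int) -> frozenset:
        if not 0 <= pos < self.length:
            raise IndexError(f"position {pos} outside [0,{self.length})")
        return self._values[bisect_right(self._starts, pos) - 1]

    def query(self, start: int, end: int) -> set:
        """All candidates overlapping [start, end) by at least one position.

        Out-of-axis queries are clamped with a warning (reads may slightly
        overhang contig ends).
        """
        if end <= start:
            raise ValueError("query interval must be non-empty")
        if start < 0 or end > self.length:
            logger.warning("query [%d,%d) clamped to axis [0,%d)",
                           start, end, self.length)
            start, end = max(0, start), min(self.length, end)
            if end <= start:
                return set()
        out: set = set()
        i = bisect_right(self._starts, start) - 1
        while i < len(self._starts) and self._starts[i] < end:
            out |= self._values[i]
            i += 1
        return out

    def to_tsv(self, ref_name: str = ".") -> str:
        """Debug dump: one line per step, `ref, start, end, candidate_ids`."""
        lines = []
        for s, e, val in self.steps():
            ids = ",".join(sorted(map(str, val))) if val else "-"
            lines.append(f"{ref_name}\t{s}\t{e}\t{ids}")
        return "\n".join(lines) + "\n"


def build_index(candidates: Iterable[CandidateHit],
                axis_lengths: Mapping[str, int]) -> dict[str, StepVector]:
    """One StepVector per reference, indexing candidate match windows."""
    per_ref: dict[str, list[tuple[int, int, CandidateHit]]] = {
        ref: [] for ref in axis_lengths}
    for cand in candidates:
        if cand.ref_name not in axis_lengths:
            raise KeyError(f"unknown reference {cand.ref_name!r}")
        per_ref[cand.ref_name].append(
            (cand.match_window[0], cand.match_window[1], cand))
    return {ref: StepVector.build(axis_lengths[ref], windows)
            for ref, windows in per_ref.items()}
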