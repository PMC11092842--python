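"""Genomic interval arithmetic.

All coordinates in this package are 0-based, half-open (BED convention):
an interval ``[start, end)`` covers ``end - start`` bases and two intervals
that merely abut (``a.end == b.start``) do not overlap. VCF input (1-based,
inclusive) is converted at the reader boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

_CHROM_ALIASES = {"M": "MT", "MT": "MT", "X": "X", "Y": "Y"}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip a leading ``chr`` and uppercase X/Y/MT.

    Annotation resources mix naming dialects (``chr1`` vs ``1``, ``chrM`` vs
    ``MT``); everything is normalized once on the way in.
    """
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name.lower().startswith("chr"):
        name = name[3:]
    upper = name.upper()
    return _CHROM_ALIASES.get(upper, name)


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - convenience alias
        return self.length


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap: min of the two mutual overlap fractions, in [0, 1].

    This is the standard criterion for matching structural variants between
    call sets; two intervals with reciprocal overlap >= 0.5 share at least
    half of each other's span.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


class OverlapIndex:
    """Indexed overlap queries over a static interval collection.

    Backed by one interval tree per chromosome. ``query`` returns every
    stored payload whose interval shares at least one base with the probe,
    in deterministic order (start, then end, then insertion order).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] | None = None, payloads: Sequence | None = None):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        if intervals is not None:
            intervals = list(intervals)
            if payloads is None:
                payloads = intervals
            if len(payloads) != len(intervals):
                raise ValueError("payloads must match intervals in length")
            for iv, payload in zip(intervals, payloads):
                self.add(iv, payload)

    def add(self, interval: GenomicInterval, payload=None) -> None:
        if payload is None:
            payload = interval
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        # insertion order is kept in the payload tuple for a stable sort
        tree[interval.start:interval.end] = (self._n, payload)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, probe: GenomicInterval) -> list:
        """All payloads overlapping ``probe`` by >= 1 bp, deterministically ordered."""
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        hits = tree.overlap(probe.start, probe.end)
        ordered = sorted(hits, key=lambda h: (h.begin, h.end, h.data[0]))
        return [h.data[1] for h in ordered]

    def query_count(self, probe: GenomicInterval) -> int:
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return 0
        return len(tree.overlap(probe.start, probe.end))


def build_index(intervals: Iterable[GenomicInterval], payloads: Sequence | None = None) -> OverlapIndex:
    """Build an :class:`OverlapIndex` from well-formed intervals."""
    return OverlapIndex(intervals, payloads)
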