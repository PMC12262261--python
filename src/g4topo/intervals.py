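"""Genomic intervals and interval algebra.

All coordinates are 0-based half-open (BED convention). Interval lists from
one source are kept sorted by (chrom, start, end); the set operations below
require sorted input and refuse to guess otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 for different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AnnotationSet:
    """A named genomic compartment (e.g. a satellite class or gene feature)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def merged(self) -> "AnnotationSet":
        return AnnotationSet(self.name, merge_intervals(self.intervals))

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def is_sorted(intervals: Sequence[GenomicInterval]) -> bool:
    return all(
        (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end)
        for a, b in zip(intervals, intervals[1:])
    )


def _require_sorted(intervals: Sequence[GenomicInterval], label: str) -> None:
    if not is_sorted(intervals):
        raise ValueError(f"{label} intervals are not sorted; sort by (chrom, start, end) first")


def merge_intervals(
    intervals: Iterable[GenomicInterval], bookend: bool = True
) -> list[GenomicInterval]:
    """Merge overlapping (and, by default, bookended) intervals, strand-agnostic."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and (
            iv.start < out[-1].end or (bookend and iv.start == out[-1].end)
        ):
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


Mode = Literal["any", "bp_overlap", "complement"]


def _pairs_overlapping(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> Iterator[tuple[int, int]]:
    """Yield (i, j) index pairs with a[i] overlapping b[j] (sorted sweep)."""
    j0 = 0
    for i, iv in enumerate(a):
        # advance j0 past b intervals that can never overlap later a's
        while j0 < len(b) and (
            (b[j0].chrom, b[j0].end) <= (iv.chrom, iv.start)
            if b[j0].chrom == iv.chrom
            else b[j0].chrom < iv.chrom
        ):
            j0 += 1
        j = j0
        while j < len(b) and b[j].chrom <= iv.chrom:
            if b[j].chrom == iv.chrom:
                if b[j].start >= iv.end:
                    break
                if iv.overlap(b[j]) > 0:
                    yield i, j
            j += 1


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    mode: Mode = "any",
):
    """Interval intersection in one of three modes.

    ``any``        -> members of *a* overlapping >=1 bp of *b*
    ``bp_overlap`` -> list of (a_interval, b_interval, overlap_bp) per pair
    ``complement`` -> members of *a* overlapping nothing in *b*
    """
    _require_sorted(a, "a")
    _require_sorted(b, "b")
    if mode == "bp_overlap":
        return [(a[i], b[j], a[i].overlap(b[j])) for i, j in _pairs_overlapping(a, b)]
    hit = set(i for i, _ in _pairs_overlapping(a, b))
    if mode == "any":
        return [iv for i, iv in enumerate(a) if i in hit]
    if mode == "complement":
        return [iv for i, iv in enumerate(a) if i not in hit]
    raise ValueError(f"unknown mode {mode!r}")


def total_overlap_bp(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Total bp of *a* covered by the merged union of *b*."""
    _require_sorted(a, "a")
    bm = merge_intervals(b)
    return sum(ov for _, _, ov in intersect(a, bm, mode="bp_overlap"))


def coverage_bp_in_window(
    window: GenomicInterval, merged: Sequence[GenomicInterval]
) -> int:
    """bp of ``window`` covered by a merged, sorted interval set."""
    return sum(window.overlap(iv) for iv in merged if iv.chrom == window.chrom)
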