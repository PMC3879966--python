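"""Strict interval algebra on genomic coordinates.

All coordinates in this package are 0-based, half-open ``[start, end)``.
The algebra is coverage-based: strand is carried but ignored, and adjacent
intervals (``a.end == b.start``) merge, so every operation is closed over
sorted, pairwise-disjoint tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "intersect_coverage",
    "subtract_intervals",
    "total_length",
    "coverage_fraction",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand, self.name
        )


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and adjacent intervals into a sorted disjoint track."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = sorted(_by_chrom(intervals)[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_coverage(
    track_a: Sequence[GenomicInterval], track_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases covered by both tracks. Inputs are merged defensively."""
    a_by = _by_chrom(merge_intervals(track_a)) if track_a else {}
    b_by = _by_chrom(merge_intervals(track_b)) if track_b else {}
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        a, b = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            s = max(a[i].start, b[j].start)
            e = min(a[i].end, b[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if a[i].end <= b[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract_intervals(
    track_a: Sequence[GenomicInterval], track_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases covered by ``track_a`` and not by ``track_b``."""
    if not track_a:
        return []
    a_by = _by_chrom(merge_intervals(track_a))
    b_by = _by_chrom(merge_intervals(track_b)) if track_b else {}
    out: list[GenomicInterval] = []
    for chrom in sorted(a_by):
        b = b_by.get(chrom, [])
        j = 0
        for iv in a_by[chrom]:
            pos = iv.start
            while j < len(b) and b[j].end <= pos:
                j += 1
            k = j
            while k < len(b) and b[k].start < iv.end:
                if b[k].start > pos:
                    out.append(GenomicInterval(chrom, pos, b[k].start))
                pos = max(pos, b[k].end)
                k += 1
            if pos < iv.end:
                out.append(GenomicInterval(chrom, pos, iv.end))
    return out


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Number of covered bases (input merged first)."""
    return sum(len(iv) for iv in merge_intervals(intervals)) if intervals else 0


def coverage_fraction(
    target: GenomicInterval, track: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``target`` bases covered by ``track``."""
    covered = total_length(intersect_coverage([target], track))
    return covered / len(target)
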