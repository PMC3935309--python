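"""Genomic interval primitives and set algebra.

All coordinates are 0-based half-open, matching BED semantics. Interval
*sets* are plain lists of :class:`GenomicInterval`; the set operations
below normalise (sort + merge) their inputs, so callers never need to
pre-sort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded); it never
    participates in equality of position-based set operations.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
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

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _by_chrom(ivs: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (bookended runs fuse)."""
    grouped = _by_chrom(ivs)
    out: list[GenomicInterval] = []
    for chrom in sorted(grouped):
        cur_s: int | None = None
        cur_e = 0
        for iv in grouped[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference ``a \\ b`` (per base), as a sorted disjoint list."""
    a_merged = merge_intervals(a)
    b_grouped = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in a_merged:
        cursor = iv.start
        for cut in b_grouped.get(iv.chrom, []):
            if cut.end <= cursor:
                continue
            if cut.start >= iv.end:
                break
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def complement_intervals(
    ivs: Iterable[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> list[GenomicInterval]:
    """Complement of the union of ``ivs`` within ``[0, size)`` per chromosome.

    Every chromosome in ``chrom_sizes`` contributes, including those with
    no input interval (whole chromosome returned).
    """
    merged = _by_chrom(merge_intervals(ivs))
    for chrom, lst in merged.items():
        if chrom not in chrom_sizes:
            raise KeyError(f"no chromosome size for {chrom!r}")
        if lst and lst[-1].end > chrom_sizes[chrom]:
            raise ValueError(
                f"interval {lst[-1].chrom}:{lst[-1].start}-{lst[-1].end} "
                f"exceeds chromosome size {chrom_sizes[chrom]}"
            )
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        cursor = 0
        for iv in merged.get(chrom, []):
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = iv.end
        if cursor < size:
            out.append(GenomicInterval(chrom, cursor, size))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base intersection of two interval sets."""
    a_merged = merge_intervals(a)
    b_grouped = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for iv in a_merged:
        for other in b_grouped.get(iv.chrom, []):
            s = max(iv.start, other.start)
            e = min(iv.end, other.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return out


def total_length(ivs: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(ivs))


def write_bed(
    ivs: Iterable[GenomicInterval],
    path,
    names: Iterable[str] | None = None,
) -> None:
    """Write intervals as BED3 (or BED4 when ``names`` is given)."""
    ivs = list(ivs)
    name_list = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            if name_list is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_list[i]}\n")
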