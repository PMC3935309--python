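"""Uniquely-mapped read ingestion and per-window counting.

Reads come from a coordinate-sorted BED (3+ columns) or BAM file. A read
is assigned to at most one window: the window containing its start
coordinate (5'-most genomic base). This guarantees conservation — no read
is ever counted twice even when it straddles a window boundary — which is
the sensible convention for short reads counted against windows several
times their length. An ``overlap`` mode (count a read once in every
window it overlaps) is available as a configuration switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .regions import Window

log = logging.getLogger(__name__)


class ReadInputError(ValueError):
    """Malformed or unsorted read input."""


@dataclass(frozen=True)
class ReadPlacement:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ReadInputError(
                f"read {self.chrom}:{self.start}-{self.end} has start >= end"
            )


def _load_bed_reads(path, chrom: str | None) -> Iterator[ReadPlacement]:
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ReadInputError(
                    f"{path}:{lineno}: BED requires >= 3 fields"
                )
            try:
                c, s, e = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ReadInputError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if s >= e:
                raise ReadInputError(
                    f"{path}:{lineno}: start {s} >= end {e}"
                )
            if last is not None:
                if c == last[0] and s < last[1]:
                    raise ReadInputError(
                        f"{path}:{lineno}: input not sorted by (chrom, start); "
                        "sort it (e.g. `sort -k1,1 -k2,2n`) and retry"
                    )
                if c != last[0] and c in seen_chroms:
                    raise ReadInputError(
                        f"{path}:{lineno}: chromosome {c} appears in multiple "
                        "blocks; input not sorted by (chrom, start)"
                    )
            if c != (last[0] if last else None):
                seen_chroms.add(c)
            last = (c, s)
            if chrom is not None and c != chrom:
                continue
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            yield ReadPlacement(c, s, e, strand)


def _load_bam_reads(path, chrom: str | None) -> Iterator[ReadPlacement]:
    import pysam

    dropped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if bam.header.get("HD", {}).get("SO") not in ("coordinate",):
            raise ReadInputError(
                f"{path}: BAM is not coordinate-sorted; run `samtools sort`"
            )
        for rec in bam.fetch(contig=chrom) if chrom and bam.has_index() else bam:
            if rec.is_unmapped:
                continue
            if chrom is not None and rec.reference_name != chrom:
                continue
            if rec.is_secondary or rec.is_supplementary or rec.mapping_quality == 0:
                dropped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            yield ReadPlacement(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
    if dropped:
        log.info("dropped %d multi-mapped/secondary records", dropped)


def load_reads(path, chrom: str | None = None) -> Iterator[ReadPlacement]:
    """Stream uniquely-mapped read placements in coordinate order.

    BED input must be sorted by (chrom, start); BAM input must be
    coordinate-sorted. Multi-mapped BAM records (secondary, supplementary
    or mapping quality 0) are dropped and the drop count logged.
    """
    if Path(path).suffix.lower() == ".bam":
        return _load_bam_reads(path, chrom)
    return _load_bed_reads(path, chrom)


def collect_starts(reads: Iterable[ReadPlacement]) -> dict[str, np.ndarray]:
    """Sorted per-chromosome arrays of read start coordinates."""
    acc: dict[str, list[int]] = {}
    for read in reads:
        acc.setdefault(read.chrom, []).append(read.start)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in acc.items()}


def _as_start_arrays(reads) -> Mapping[str, np.ndarray]:
    if isinstance(reads, Mapping):
        return reads
    return collect_starts(reads)


def count_reads_in_windows(
    reads,
    windows: list[Window],
    mode: str = "start",
) -> list[Window]:
    """Fill ``count`` for each window; returns the same list.

    ``reads`` is a placement iterable or a ``{chrom: sorted start array}``
    mapping (``mode="overlap"`` requires placements, since it needs read
    ends). Windows must be sorted and disjoint within each chromosome.
    In ``start`` mode each read counts in the unique window containing
    its start; reads starting outside every window are ignored.
    """
    if mode not in ("start", "overlap"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if mode == "overlap":
        return _count_overlap(reads, windows)
    starts = _as_start_arrays(reads)
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, wins in by_chrom.items():
        arr = starts.get(chrom)
        if arr is None or arr.size == 0:
            for w in wins:
                w.count = 0
            continue
        w_starts = np.asarray([w.start for w in wins], dtype=np.int64)
        w_ends = np.asarray([w.end for w in wins], dtype=np.int64)
        lo = np.searchsorted(arr, w_starts, side="left")
        hi = np.searchsorted(arr, w_ends, side="left")
        for w, c in zip(wins, (hi - lo).tolist()):
            w.count = c
    return windows


def _count_overlap(reads, windows: list[Window]) -> list[Window]:
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        w.count = 0
        by_chrom.setdefault(w.chrom, []).append(w)
    placements: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    acc: dict[str, list[tuple[int, int]]] = {}
    for read in reads:
        acc.setdefault(read.chrom, []).append((read.start, read.end))
    for chrom, pairs in acc.items():
        arr = np.asarray(pairs, dtype=np.int64)
        placements[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
    for chrom, wins in by_chrom.items():
        if chrom not in placements:
            continue
        starts_sorted, ends_sorted = placements[chrom]
        for w in wins:
            # overlap <=> read.start < w.end and read.end > w.start
            n_start_before_end = np.searchsorted(starts_sorted, w.end, side="left")
            n_end_at_or_before_start = np.searchsorted(
                ends_sorted, w.start, side="right"
            )
            w.count = int(n_start_before_end - n_end_at_or_before_start)
    return windows


def write_bedgraph(windows: list[Window], path) -> None:
    """Write window counts as BEDGRAPH (for genome-browser loading)."""
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    with open(path, "w") as fh:
        for w in ordered:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.count}\n")
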