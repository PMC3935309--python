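"""Synthetic annotation, read and junction generator with known truth.

Emulates the inputs of the discovery workflow at desk scale: a single
small chromosome carrying a handful of multi-exon, multi-isoform genes;
uniquely-mapped 50 bp read starts drawn as a Poisson process — a uniform
background everywhere, an elevated rate over exons (expressed genes) and
a fold-enriched rate inside planted intronic/intergenic regions (the
unannotated transcription the caller must find); and a junctions.bed
with junctions constructed to satisfy each classification category.

Everything is driven by one integer seed; the same configuration always
produces byte-identical output files. What the generator does *not*
emulate: sequencing error, mappability gaps, fragment-length structure
and non-uniform (GC/position-biased) coverage — see the package docs for
what that implies about the closed-loop tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals, subtract_intervals
from .junctions import Junction
from .regions import (
    AnnotationIndex,
    Exon,
    Gene,
    Transcript,
    derive_compartments,
)


class SimulationError(ValueError):
    """Requested structure cannot be placed in the configured genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults describe a 2 Mb toy chromosome with six expressed genes and
    a mapped-read density of 0.01 reads/bp — the read density of a
    chromosome-restricted slice of a typical bulk RNA-seq library — with
    twenty planted transcribed regions at 10-fold enrichment spanning
    3-10 windows each.
    """

    seed: int = 0
    chrom: str = "chr21"
    chrom_length: int = 2_000_000
    n_genes: int = 6
    exons_per_transcript: tuple[int, int] = (3, 5)
    isoforms_per_gene: tuple[int, int] = (1, 2)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (3_000, 12_000)
    intergenic_gap: tuple[int, int] = (30_000, 80_000)
    background_rate: float = 0.01  # reads per bp
    exon_fold: float = 20.0  # exonic rate = fold * background
    read_length: int = 50
    n_planted_regions: int = 20
    planted_fold: float = 10.0
    planted_len_windows: tuple[int, int] = (3, 10)
    intronic_window: int = 200
    intergenic_window: int = 500
    planted_edge_margin_windows: int = 1
    junctions_per_category: dict[int, int] = field(
        default_factory=lambda: {c: 1 for c in range(1, 8)}
    )
    junction_support: tuple[int, int] = (3, 50)

    def __post_init__(self) -> None:
        if self.planted_fold <= 1:
            raise ValueError("planted fold enrichment must be > 1")
        if self.n_planted_regions < 0 or self.n_genes < 0:
            raise ValueError("counts must be >= 0")
        if self.chrom_length <= 0:
            raise ValueError("chromosome length must be positive")


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimulationConfig) -> AnnotationIndex:
    """Place non-overlapping multi-isoform genes along the chromosome."""
    rng = np.random.default_rng(cfg.seed)
    chrom_sizes = {cfg.chrom: cfg.chrom_length}
    genes: dict[str, Gene] = {}
    cursor = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
    for gi in range(cfg.n_genes):
        gid = f"SIMG{gi + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(
            rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1)
        )
        # primary isoform: alternating exons and introns
        exon_ivs: list[GenomicInterval] = []
        pos = cursor
        for ei in range(n_exons):
            elen = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exon_ivs.append(GenomicInterval(cfg.chrom, pos, pos + elen, strand))
            pos += elen
            if ei < n_exons - 1:
                pos += int(
                    rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)
                )
        if pos >= cfg.chrom_length:
            raise SimulationError(
                f"gene {gid} does not fit: chromosome too short for the "
                "configured gene structure"
            )
        gene = Gene(gene_id=gid, name=f"SIMGENE{gi + 1}", strand=strand)
        # the first gene always carries the maximum isoform count so that
        # isoform-dependent junction categories are constructible
        if gi == 0:
            n_iso = cfg.isoforms_per_gene[1]
        else:
            n_iso = int(
                rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1)
            )
        for ti in range(n_iso):
            tid = f"SIMT{gi + 1:03d}.{ti + 1}"
            if ti == 0 or n_exons < 3:
                ivs = list(exon_ivs)
            else:
                # alternative isoform: skip one internal exon and add a
                # private exon inside an intron, so isoform-specific exons
                # exist (needed to exercise the different-transcripts
                # junction category)
                skip = int(rng.integers(1, n_exons - 1))
                ivs = [iv for k, iv in enumerate(exon_ivs) if k != skip]
                # private exon placed a fixed 500 bp into the upstream
                # intron: intron lengths guarantee it never touches the
                # skipped exon, so each isoform owns an exclusive exon
                left = exon_ivs[skip - 1]
                estart = left.end + 500
                private = GenomicInterval(cfg.chrom, estart, estart + 120, strand)
                if private.end <= exon_ivs[skip].start:
                    ivs.append(private)
                    ivs.sort(key=lambda iv: iv.start)
            tx = Transcript(transcript_id=tid, gene_id=gid, strand=strand)
            n = len(ivs)
            for k, iv in enumerate(ivs):
                rank = k + 1 if strand != "-" else n - k
                tx.exons.append(Exon(gid, tid, rank, iv))
            gene.transcripts[tid] = tx
        genes[gid] = gene
        cursor = pos + int(
            rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1)
        )
        if cursor >= cfg.chrom_length:
            raise SimulationError(
                "genes do not fit in the chromosome; increase chrom_length or "
                "reduce n_genes"
            )
    return AnnotationIndex(genes, chrom_sizes)


def write_gtf(ann: AnnotationIndex, path) -> None:
    """Write the annotation as GENCODE-dialect GTF (1-based closed)."""
    lines = []
    for gid in sorted(ann.genes):
        gene = ann.genes[gid]
        span = gene.span
        attrs = f'gene_id "{gid}"; gene_name "{gene.name}";'
        lines.append(
            f"{span.chrom}\tsim\tgene\t{span.start + 1}\t{span.end}\t.\t"
            f"{gene.strand}\t.\t{attrs}"
        )
        for tid in sorted(gene.transcripts):
            tx = gene.transcripts[tid]
            tspan = tx.span
            tattrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; '
                f'gene_name "{gene.name}";'
            )
            lines.append(
                f"{tspan.chrom}\tsim\ttranscript\t{tspan.start + 1}\t{tspan.end}"
                f"\t.\t{tx.strand}\t.\t{tattrs}"
            )
            for exon in tx.exons:
                iv = exon.interval
                eattrs = tattrs + f' exon_number "{exon.rank}";'
                lines.append(
                    f"{iv.chrom}\tsim\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{tx.strand}\t.\t{eattrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_chrom_sizes(ann: AnnotationIndex, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"{chrom}\t{ann.chrom_sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# reads


def plant_regions(
    cfg: SimulationConfig, ann: AnnotationIndex, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose planted transcribed regions inside introns and intergenic gaps.

    Regions are whole numbers of windows long, aligned to the window grid
    of their compartment, kept at least ``planted_edge_margin_windows``
    windows from compartment edges, and mutually non-overlapping.
    """
    comp = derive_compartments(ann)
    rows = []
    taken: list[GenomicInterval] = []
    compartments = [
        ("intronic", comp.intronic, cfg.intronic_window),
        ("intergenic", comp.intergenic, cfg.intergenic_window),
    ]
    for i in range(cfg.n_planted_regions):
        name, ivs, window = compartments[i % 2]
        n_windows = int(
            rng.integers(cfg.planted_len_windows[0], cfg.planted_len_windows[1] + 1)
        )
        length = n_windows * window
        margin = cfg.planted_edge_margin_windows * window
        placed = False
        for _ in range(200):
            candidates = [
                iv for iv in subtract_intervals(ivs, taken)
                if iv.length >= length + 2 * margin
            ]
            if not candidates:
                break
            iv = candidates[int(rng.integers(len(candidates)))]
            # snap to the window grid of the host compartment interval
            host = next(h for h in ivs if h.contains(iv))
            lo_slot = (iv.start + margin - host.start + window - 1) // window
            hi_slot = (iv.end - margin - length - host.start) // window
            if hi_slot < lo_slot:
                continue
            slot = int(rng.integers(lo_slot, hi_slot + 1))
            start = host.start + slot * window
            region = GenomicInterval(iv.chrom, start, start + length)
            if any(region.overlaps(t) for t in taken):
                continue
            taken.append(region)
            # margin interval reserved around the region so plants stay
            # separated by more than one window (distinct HCPs)
            taken.append(
                GenomicInterval(
                    iv.chrom, max(0, start - 2 * window), start + length + 2 * window
                )
            )
            rows.append(
                {
                    "region_id": f"PLANT{i + 1:03d}",
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "compartment": name,
                    "n_windows": n_windows,
                    "fold": cfg.planted_fold,
                }
            )
            placed = True
            break
        if not placed:
            raise SimulationError(
                f"could not place planted region {i + 1} "
                f"({length} bp {name}); enlarge the genome or reduce the count"
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "chrom", "start", "end", "compartment",
            "n_windows", "fold",
        ],
    )


def simulate_reads(
    cfg: SimulationConfig, ann: AnnotationIndex
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw read placements; returns (reads table, planted-region truth).

    Read starts are a Poisson process: ``background_rate`` everywhere,
    ``exon_fold`` x over exon bases and ``planted_fold`` x inside planted
    regions. Reads are ``read_length`` bp, clipped at the chromosome end.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    truth = (
        plant_regions(cfg, ann, rng)
        if cfg.n_planted_regions > 0
        else pd.DataFrame(
            columns=[
                "region_id", "chrom", "start", "end", "compartment",
                "n_windows", "fold",
            ]
        )
    )
    starts: list[np.ndarray] = []
    size = cfg.chrom_length

    def _draw(iv_start: int, iv_end: int, rate: float) -> None:
        n = rng.poisson(rate * (iv_end - iv_start))
        if n:
            starts.append(rng.integers(iv_start, iv_end, size=n))

    # uniform background across the whole chromosome
    _draw(0, size, cfg.background_rate)
    # extra reads over exons (expressed annotated genes)
    for iv in merge_intervals([e.interval for e in ann.exons()]):
        _draw(iv.start, iv.end, cfg.background_rate * (cfg.exon_fold - 1))
    # extra reads inside planted regions
    for row in truth.itertuples():
        _draw(row.start, row.end, cfg.background_rate * (cfg.planted_fold - 1))

    if starts:
        all_starts = np.sort(np.concatenate(starts))
    else:
        all_starts = np.empty(0, dtype=np.int64)
    ends = np.minimum(all_starts + cfg.read_length, size)
    reads = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": all_starts,
            "end": ends,
            "name": [f"read{i + 1}" for i in range(all_starts.size)],
            "score": 0,
            "strand": np.where(
                rng.random(all_starts.size) < 0.5, "+", "-"
            ),
        }
    )
    return reads, truth


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# junctions


def _transcripts_with_exons(ann: AnnotationIndex, n: int) -> list[Transcript]:
    return [tx for tx in ann.transcripts() if len(tx.exons) >= n]


def _exon_union(ann: AnnotationIndex) -> list[GenomicInterval]:
    return merge_intervals([e.interval for e in ann.exons()])


def _free_block(
    region: GenomicInterval, exon_union: Sequence[GenomicInterval], width: int = 20
) -> GenomicInterval | None:
    """A width-bp block inside ``region`` overlapping no exon."""
    free = subtract_intervals([region], exon_union)
    for iv in free:
        if iv.length >= width + 2:
            mid = (iv.start + iv.end - width) // 2
            return GenomicInterval(iv.chrom, mid, mid + width)
    return None


def simulate_junctions(
    cfg: SimulationConfig, ann: AnnotationIndex
) -> tuple[list[Junction], pd.DataFrame]:
    """Construct junctions satisfying each requested category.

    Each junction is built so that, under the documented hierarchy, it
    belongs to exactly the intended category; the truth table records
    that intent. Raises :class:`SimulationError` naming the first
    category the annotation cannot support.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    exon_union = _exon_union(ann)
    comp = derive_compartments(ann)
    junctions: list[Junction] = []
    rows = []
    counter = 0

    def _support() -> int:
        return int(rng.integers(cfg.junction_support[0], cfg.junction_support[1] + 1))

    def _emit(category: int, left: GenomicInterval, right: GenomicInterval,
              strand: str) -> None:
        nonlocal counter
        counter += 1
        junctions.append(
            Junction(
                chrom=left.chrom, start=left.start, end=right.end, strand=strand,
                mol=left.length, mor=right.length, support=_support(),
                name=f"SIMJ{counter:04d}",
            )
        )
        rows.append(
            {
                "junction_id": f"SIMJ{counter:04d}",
                "chrom": left.chrom,
                "start": left.start,
                "end": right.end,
                "category": category,
            }
        )

    for category in sorted(cfg.junctions_per_category):
        n_wanted = cfg.junctions_per_category[category]
        for _ in range(n_wanted):
            built = _build_junction(category, ann, comp, exon_union, rng, _emit)
            if not built:
                raise SimulationError(
                    f"annotation cannot support a category-{category} junction"
                )
    truth = pd.DataFrame(
        rows, columns=["junction_id", "chrom", "start", "end", "category"]
    )
    return junctions, truth


def _edge_blocks(
    left_exon: GenomicInterval, right_exon: GenomicInterval, width: int = 20
) -> tuple[GenomicInterval, GenomicInterval]:
    w_l = min(width, left_exon.length)
    w_r = min(width, right_exon.length)
    left = GenomicInterval(left_exon.chrom, left_exon.end - w_l, left_exon.end)
    right = GenomicInterval(right_exon.chrom, right_exon.start, right_exon.start + w_r)
    return left, right


def _blocks_adjacent_in_some_transcript(
    ann: AnnotationIndex, left: GenomicInterval, right: GenomicInterval
) -> bool:
    """True if some transcript has the two blocks in consecutive exons."""
    for tx in ann.transcripts():
        ivs = [e.interval for e in tx.exons]
        li = [i for i, iv in enumerate(ivs) if iv.overlaps(left)]
        ri = [i for i, iv in enumerate(ivs) if iv.overlaps(right)]
        if any(j - i == 1 for i in li for j in ri):
            return True
    return False


def _blocks_share_transcript(
    ann: AnnotationIndex, left: GenomicInterval, right: GenomicInterval
) -> bool:
    for tx in ann.transcripts():
        ivs = [e.interval for e in tx.exons]
        if any(iv.overlaps(left) for iv in ivs) and any(
            iv.overlaps(right) for iv in ivs
        ):
            return True
    return False


def _build_junction(category, ann, comp, exon_union, rng, emit) -> bool:
    if category == 1:
        for tx in _transcripts_with_exons(ann, 2):
            exons = [e.interval for e in tx.exons]
            left, right = _edge_blocks(exons[0], exons[1])
            if left.end <= right.start:
                emit(1, left, right, tx.strand)
                return True
        return False
    if category == 2:
        for tx in _transcripts_with_exons(ann, 3):
            exons = [e.interval for e in tx.exons]
            n = len(exons)
            for i in range(n):
                for j in range(i + 2, n):
                    left, right = _edge_blocks(exons[i], exons[j])
                    if left.end >= right.start:
                        continue
                    # another isoform may hold this pair as consecutive
                    # exons, which would make the junction annotated
                    if _blocks_adjacent_in_some_transcript(ann, left, right):
                        continue
                    emit(2, left, right, tx.strand)
                    return True
        return False
    if category == 3:
        # left anchor in an exon, right anchor in exon-free intron space
        for tx in _transcripts_with_exons(ann, 2):
            exons = [e.interval for e in tx.exons]
            intron = GenomicInterval(tx.chrom, exons[0].end, exons[1].start)
            right = _free_block(intron, exon_union)
            if right is None:
                continue
            left = GenomicInterval(tx.chrom, exons[0].end - 20, exons[0].end)
            if left.end + 10 <= right.start:
                emit(3, left, right, tx.strand)
                return True
        return False
    if category == 4:
        for exon in (e.interval for e in ann.exons()):
            if exon.length >= 80:
                left = GenomicInterval(exon.chrom, exon.start + 5, exon.start + 25)
                right = GenomicInterval(exon.chrom, exon.end - 25, exon.end - 5)
                if left.end < right.start:
                    strand = exon.strand if exon.strand in "+-" else "+"
                    emit(4, left, right, strand)
                    return True
        return False
    if category == 5:
        for gene in ann.genes.values():
            txs = list(gene.transcripts.values())
            for a in txs:
                for b in txs:
                    if a.transcript_id == b.transcript_id:
                        continue
                    b_cover = [e.interval for e in b.exons]
                    a_only = [
                        e.interval for e in a.exons
                        if not any(e.interval.overlaps(x) for x in b_cover)
                    ]
                    a_cover = [e.interval for e in a.exons]
                    b_only = [
                        e.interval for e in b.exons
                        if not any(e.interval.overlaps(x) for x in a_cover)
                    ]
                    for ea in a_only:
                        for eb in b_only:
                            if ea.end + 10 < eb.start:
                                left, right = _edge_blocks(ea, eb)
                                if (
                                    left.end < right.start
                                    and not _blocks_share_transcript(
                                        ann, left, right
                                    )
                                ):
                                    emit(5, left, right, gene.strand)
                                    return True
        return False
    if category == 6:
        ordered = sorted(ann.genes.values(), key=lambda g: g.span.start)
        for g1, g2 in zip(ordered, ordered[1:]):
            if g1.chrom != g2.chrom or g1.span.end >= g2.span.start:
                continue
            e1 = max((e.interval for e in _gene_exons(g1)), key=lambda iv: iv.end)
            e2 = min((e.interval for e in _gene_exons(g2)), key=lambda iv: iv.start)
            left, right = _edge_blocks(e1, e2)
            if left.end < right.start:
                emit(6, left, right, g1.strand)
                return True
        return False
    if category == 7:
        for pool in (comp.intergenic, comp.intronic):
            for iv in pool:
                if iv.length >= 2_000:
                    left = _free_block(
                        GenomicInterval(iv.chrom, iv.start, iv.start + iv.length // 2),
                        exon_union,
                    )
                    right = _free_block(
                        GenomicInterval(iv.chrom, iv.start + iv.length // 2, iv.end),
                        exon_union,
                    )
                    if left and right and left.end + 10 <= right.start:
                        emit(7, left, right, "+")
                        return True
        return False
    raise ValueError(f"unknown category {category}")


def _gene_exons(gene: Gene):
    for tx in gene.transcripts.values():
        yield from tx.exons


def write_junctions_bed(junctions: Sequence[Junction], path) -> None:
    """Write junctions in the TopHat junctions.bed dialect."""
    with open(path, "w") as fh:
        for j in junctions:
            block_starts = f"0,{(j.end - j.mor) - j.start}"
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.name}\t{j.support}\t"
                f"{j.strand}\t{j.start}\t{j.end}\t255,0,0\t2\t"
                f"{j.mol},{j.mor}\t{block_starts}\n"
            )


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(cfg: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write the full synthetic dataset; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = simulate_annotation(cfg)
    reads, truth_regions = simulate_reads(cfg, ann)
    junctions, truth_junctions = simulate_junctions(cfg, ann)
    paths = {
        "chrom_sizes": out / "genome.chrom.sizes",
        "annotation": out / "annotation.gtf",
        "reads": out / "reads.bed",
        "junctions": out / "junctions.bed",
        "truth_regions": out / "truth_regions.tsv",
        "truth_junctions": out / "truth_junctions.tsv",
    }
    write_chrom_sizes(ann, paths["chrom_sizes"])
    write_gtf(ann, paths["annotation"])
    write_reads_bed(reads, paths["reads"])
    write_junctions_bed(junctions, paths["junctions"])
    truth_regions.to_csv(paths["truth_regions"], sep="\t", index=False)
    truth_junctions.to_csv(paths["truth_junctions"], sep="\t", index=False)
    return paths
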