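"""Annotation ingestion and region derivation.

Builds a genes -> transcripts -> exons index from a GENCODE-dialect GTF
or a BED12 file, derives the intronic / intergenic compartments, selects
background-eligible regions for rate estimation, and tiles regions into
fixed-width windows.

Coordinate conventions: everything is stored 0-based half-open. GTF input
(1-based closed) is converted on load; BED input is taken as-is.

The intronic compartment is defined locus-wide: a base is intronic iff it
is covered by at least one transcript span and by no exon of *any*
transcript. The intergenic compartment is the chromosome complement of
the union of gene spans. These definitions guarantee that windows tiled
over either compartment never overlap an annotated exon, which is what a
search for unannotated transcription requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .intervals import (
    GenomicInterval,
    complement_intervals,
    merge_intervals,
    subtract_intervals,
)


class AnnotationError(ValueError):
    """Malformed or structurally invalid annotation input."""


@dataclass(frozen=True)
class Exon:
    gene_id: str
    transcript_id: str
    rank: int  # 1..n in transcription order (reversed genomic order on -)
    interval: GenomicInterval


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[Exon] = field(default_factory=list)  # sorted by genomic start

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].interval.start,
            self.exons[-1].interval.end, self.strand,
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons of this transcript."""
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if left.interval.end < right.interval.start:
                out.append(
                    GenomicInterval(
                        self.chrom, left.interval.end, right.interval.start,
                        self.strand,
                    )
                )
        return out


@dataclass
class Gene:
    gene_id: str
    name: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def chrom(self) -> str:
        return next(iter(self.transcripts.values())).chrom

    @property
    def span(self) -> GenomicInterval:
        starts = [t.span.start for t in self.transcripts.values()]
        ends = [t.span.end for t in self.transcripts.values()]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)


class AnnotationIndex:
    """Genes, transcripts and ranked exons plus chromosome sizes.

    Exon interval queries (used heavily by the junction classifier) are
    served from per-chromosome interval trees built lazily.
    """

    def __init__(self, genes: dict[str, Gene], chrom_sizes: Mapping[str, int]):
        self.genes = genes
        self.chrom_sizes = dict(chrom_sizes)
        self._exon_trees: dict[str, IntervalTree] | None = None
        self._validate()

    def _validate(self) -> None:
        for gene in self.genes.values():
            for tx in gene.transcripts.values():
                prev_end = -1
                for exon in tx.exons:
                    if exon.interval.start < prev_end:
                        raise AnnotationError(
                            f"transcript {tx.transcript_id}: exon "
                            f"{exon.interval.start}-{exon.interval.end} overlaps "
                            "the previous exon of the same transcript"
                        )
                    prev_end = exon.interval.end
                # transcription-order ranks must reverse genomic order on -
                ranks = [e.rank for e in tx.exons]
                expected = (
                    list(range(1, len(ranks) + 1))
                    if tx.strand != "-"
                    else list(range(len(ranks), 0, -1))
                )
                if ranks != expected:
                    raise AnnotationError(
                        f"transcript {tx.transcript_id}: exon ranks {ranks} do "
                        f"not follow transcription order for strand {tx.strand}"
                    )
            span = gene.span
            size = self.chrom_sizes.get(gene.chrom)
            if size is not None and span.end > size:
                raise AnnotationError(
                    f"gene {gene.gene_id} span {span.start}-{span.end} exceeds "
                    f"chromosome size {size}"
                )

    # -- queries ---------------------------------------------------------

    def transcripts(self) -> Iterable[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def exons(self) -> Iterable[Exon]:
        for tx in self.transcripts():
            yield from tx.exons

    def gene_spans(self) -> list[GenomicInterval]:
        return [g.span for g in self.genes.values()]

    def exon_tree(self, chrom: str) -> IntervalTree:
        if self._exon_trees is None:
            trees: dict[str, IntervalTree] = {}
            for exon in self.exons():
                tree = trees.setdefault(exon.interval.chrom, IntervalTree())
                tree.addi(exon.interval.start, exon.interval.end, exon)
            self._exon_trees = trees
        return self._exon_trees.get(chrom, IntervalTree())


# ---------------------------------------------------------------------------
# loaders


def load_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 'chrom length', got {line!r}"
                )
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from exc
    return sizes


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _load_gtf(path, chrom_sizes: Mapping[str, int]) -> AnnotationIndex:
    # gffutils is the canonical parser for GENCODE-dialect GTF; an
    # in-memory db avoids any on-disk artefact.
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    genes: dict[str, Gene] = {}
    tx_by_id: dict[str, Transcript] = {}

    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        name = feat.attributes.get("gene_name", [gid])[0]
        genes[gid] = Gene(gene_id=gid, name=name, strand=feat.strand)
    for feat in db.features_of_type("transcript"):
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes["transcript_id"][0]
        if gid not in genes:
            genes[gid] = Gene(gene_id=gid, name=gid, strand=feat.strand)
        tx = Transcript(transcript_id=tid, gene_id=gid, strand=feat.strand)
        genes[gid].transcripts[tid] = tx
        tx_by_id[tid] = tx
    for feat in db.features_of_type("exon"):
        tid_attr = feat.attributes.get("transcript_id")
        if not tid_attr:
            raise AnnotationError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                "a transcript_id attribute"
            )
        tid = tid_attr[0]
        if tid not in tx_by_id:
            raise AnnotationError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                f"references unknown transcript {tid!r}"
            )
        tx = tx_by_id[tid]
        # GTF is 1-based closed; convert to 0-based half-open.
        tx.exons.append(
            Exon(
                gene_id=tx.gene_id,
                transcript_id=tid,
                rank=0,  # assigned after sorting
                interval=GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, feat.strand
                ),
            )
        )

    for tx in tx_by_id.values():
        if not tx.exons:
            raise AnnotationError(
                f"{path}: transcript {tx.transcript_id} has no exons"
            )
        tx.exons.sort(key=lambda e: e.interval.start)
        _assign_ranks(tx)
    genes = {g: gene for g, gene in genes.items() if gene.transcripts}
    return AnnotationIndex(genes, chrom_sizes)


def _assign_ranks(tx: Transcript) -> None:
    n = len(tx.exons)
    ranked = []
    for i, exon in enumerate(tx.exons):
        rank = i + 1 if tx.strand != "-" else n - i
        ranked.append(
            Exon(exon.gene_id, exon.transcript_id, rank, exon.interval)
        )
    tx.exons = ranked


def _load_bed12(path, chrom_sizes: Mapping[str, int]) -> AnnotationIndex:
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: BED12 requires 12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5] if fields[5] in ("+", "-") else "."
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed BED12 record: {exc}"
                ) from exc
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount={block_count} does not match "
                    "blockSizes/blockStarts"
                )
            tid = name
            gid = name
            gene = genes.setdefault(gid, Gene(gene_id=gid, name=gid, strand=strand))
            tx = Transcript(transcript_id=tid, gene_id=gid, strand=strand)
            for bs, bl in zip(block_starts, block_sizes):
                start = chrom_start + bs
                tx.exons.append(
                    Exon(gid, tid, 0, GenomicInterval(chrom, start, start + bl, strand))
                )
            tx.exons.sort(key=lambda e: e.interval.start)
            _assign_ranks(tx)
            gene.transcripts[tid] = tx
    return AnnotationIndex(genes, chrom_sizes)


def load_annotation(path, chrom_sizes) -> AnnotationIndex:
    """Load a GTF (GENCODE dialect) or BED12 annotation.

    ``chrom_sizes`` may be a mapping or a path to a two-column table.
    Format is chosen by extension (``.gtf``/``.gff`` vs ``.bed``).
    """
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = load_chrom_sizes(chrom_sizes)
    suffix = Path(path).suffix.lower()
    if suffix in (".bed", ".bed12"):
        return _load_bed12(path, chrom_sizes)
    return _load_gtf(path, chrom_sizes)


# ---------------------------------------------------------------------------
# compartments


@dataclass
class CompartmentSet:
    """Disjoint intronic / intergenic / genic interval sets."""

    intronic: list[GenomicInterval]
    intergenic: list[GenomicInterval]
    genic: list[GenomicInterval]


def derive_introns(ann: AnnotationIndex) -> list[GenomicInterval]:
    """Locus-wide intronic compartment.

    A base is intronic iff it lies inside some transcript span and inside
    no exon of any transcript (of any gene), so overlapping isoforms and
    nested genes never leak exonic bases into the compartment.
    """
    spans = [tx.span for tx in ann.transcripts()]
    exons = [e.interval for e in ann.exons()]
    return subtract_intervals(spans, exons)


def derive_intergenic(ann: AnnotationIndex) -> list[GenomicInterval]:
    """Complement of the union of gene spans within each chromosome."""
    return complement_intervals(ann.gene_spans(), ann.chrom_sizes)


def derive_compartments(ann: AnnotationIndex) -> CompartmentSet:
    return CompartmentSet(
        intronic=derive_introns(ann),
        intergenic=derive_intergenic(ann),
        genic=merge_intervals(ann.gene_spans()),
    )


def select_background_regions(
    comp: CompartmentSet,
    intergenic_min_len: int = 1_000_000,
    intergenic_trim: int = 10_000,
    intronic_min_len: int = 300_000,
    intronic_trim: int = 1_000,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Background-eligible regions for rate estimation.

    Intergenic intervals longer than ``intergenic_min_len`` are kept,
    shrunk by ``intergenic_trim`` at both ends (keeping the estimate away
    from gene boundaries); intronic intervals longer than
    ``intronic_min_len`` are kept, shrunk by ``intronic_trim`` (away from
    exon boundaries). Length eligibility is judged on the untrimmed
    interval. Either returned set may be empty.
    """
    for min_len, trim, label in (
        (intergenic_min_len, intergenic_trim, "intergenic"),
        (intronic_min_len, intronic_trim, "intronic"),
    ):
        if trim * 2 >= min_len:
            raise ValueError(
                f"{label} trim {trim} must be smaller than half the minimum "
                f"length {min_len}"
            )

    def _select(ivs, min_len, trim):
        out = []
        for iv in ivs:
            if iv.length > min_len:
                out.append(GenomicInterval(iv.chrom, iv.start + trim, iv.end - trim))
        return out

    intronic_bg = _select(comp.intronic, intronic_min_len, intronic_trim)
    intergenic_bg = _select(comp.intergenic, intergenic_min_len, intergenic_trim)
    return intronic_bg, intergenic_bg


# ---------------------------------------------------------------------------
# windows


@dataclass
class Window:
    """A fixed-width tile of a compartment, later annotated with statistics.

    ``end - start`` is the *true* width (the trailing tile of a region may
    be shorter than ``nominal_width``); expected counts are always scaled
    by the true width.
    """

    chrom: str
    start: int
    end: int
    compartment: str = "."
    nominal_width: int = 0
    count: int = 0
    mu: float = math.nan
    p: float = math.nan
    q: float = math.nan
    significant: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def is_partial(self) -> bool:
        return self.width < self.nominal_width

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def make_windows(
    regions: Iterable[GenomicInterval], width: int, compartment: str = "."
) -> list[Window]:
    """Tile each region left-to-right into ``width``-bp windows.

    A final partial tile is kept (its true width is ``end - start``);
    tiles never span two regions.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    windows: list[Window] = []
    for region in merge_intervals(regions):
        pos = region.start
        while pos < region.end:
            end = min(pos + width, region.end)
            windows.append(
                Window(region.chrom, pos, end, compartment=compartment,
                       nominal_width=width)
            )
            pos = end
    return windows
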