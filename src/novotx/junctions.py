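"""Splice-junction model and hierarchical seven-category classifier.

A junction j is a pair of exonic anchor blocks, left (L_j) and right
(R_j), separated by the spliced-out gap. In the TopHat junctions.bed
dialect (BED12, two blocks) the junction span runs from chromStart (S)
to chromEnd (E); the block lengths are the maximal overhangs (MOL, MOR)
over all reads spanning the junction, so L = [S, S+MOL) and
R = [E-MOR, E). The score field carries the number of supporting reads.

Each block is intersected with every annotated exon (>= 1 bp overlap,
strand-blind, intersectBed semantics) and the junction is assigned the
first category it satisfies in a fixed hierarchy:

1. annotated            — L and R hit consecutive exons of one transcript
2. exon skipping        — L and R hit non-consecutive exons of one transcript
3. only one side        — exactly one block hits an exon
4. intra-exonic         — both blocks hit (only) the same single exon
5. different transcripts— L and R hit exons of two different transcripts
                          of the same gene (no one transcript holds both)
6. trans-splicing       — L and R hit exons of two different genes
7. intronic/intergenic  — neither block hits any exon

"Consecutive" means adjacent in genomic order within one transcript,
which is equivalent to adjacency in transcription order on either
strand. The hierarchy makes the categories mutually exclusive and
exhaustive: a junction annotated for one transcript but skipping for
another is category 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval
from .regions import AnnotationIndex, Exon

log = logging.getLogger(__name__)

CATEGORY_NAMES: dict[int, str] = {
    1: "annotated",
    2: "exon_skipping",
    3: "only_one_side",
    4: "intra_exonic",
    5: "different_transcripts",
    6: "trans_splicing",
    7: "intronic_intergenic",
}


@dataclass(frozen=True)
class Junction:
    """A splice junction with maximal-overhang anchor blocks."""

    chrom: str
    start: int  # S: junction start (left block start)
    end: int  # E: junction end (right block end)
    strand: str
    mol: int  # left maximal-overhang length
    mor: int  # right maximal-overhang length
    support: int
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.mol < 1 or self.mor < 1:
            raise ValueError("maximal overhangs must be >= 1 bp")
        if self.support < 0:
            raise ValueError("support must be >= 0")
        if self.start + self.mol > self.end - self.mor:
            raise ValueError(
                f"junction {self.chrom}:{self.start}-{self.end}: blocks overlap "
                "(no intron gap)"
            )

    @property
    def left_block(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.start + self.mol)

    @property
    def right_block(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.end - self.mor, self.end)


@dataclass(frozen=True)
class ExonHit:
    gene_id: str
    transcript_id: str
    rank: int  # transcription-order rank
    genomic_index: int  # 0-based position of the exon in genomic order
    exon: GenomicInterval
    overlap: int


@dataclass
class JunctionCall:
    junction: Junction
    category: int
    evidence: dict

    @property
    def category_name(self) -> str:
        return CATEGORY_NAMES[self.category]


# ---------------------------------------------------------------------------
# loading


def load_junctions(path, deduplicate: bool = True) -> list[Junction]:
    """Parse a TopHat-dialect junctions.bed (BED12, two blocks each).

    Records with blockCount != 2 or overlapping blocks are rejected with
    a warning. Duplicate junctions — same (chrom, start, end, strand) —
    are merged: supports summed, overhangs maximised.
    """
    junctions: list[Junction] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                log.warning("%s:%d: not BED12; record rejected", path, lineno)
                n_rejected += 1
                continue
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                support = int(float(fields[4]))
                strand = fields[5] if fields[5] in ("+", "-") else "."
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                log.warning("%s:%d: malformed record rejected", path, lineno)
                n_rejected += 1
                continue
            if block_count != 2 or len(sizes) != 2 or len(offsets) != 2:
                log.warning(
                    "%s:%d: blockCount=%s != 2; record rejected",
                    path, lineno, block_count,
                )
                n_rejected += 1
                continue
            if offsets[1] + sizes[1] != end - start or offsets[0] != 0:
                # tolerate, but derive blocks from the BED12 fields directly
                pass
            try:
                junctions.append(
                    Junction(
                        chrom=chrom, start=start, end=end, strand=strand,
                        mol=sizes[0], mor=sizes[1], support=support, name=name,
                    )
                )
            except ValueError as exc:
                log.warning("%s:%d: %s; record rejected", path, lineno, exc)
                n_rejected += 1
    if n_rejected:
        log.info("rejected %d junction records", n_rejected)
    if deduplicate:
        junctions = deduplicate_junctions(junctions)
    return junctions


def deduplicate_junctions(junctions: Iterable[Junction]) -> list[Junction]:
    """Merge records sharing (chrom, start, end, strand).

    Supports are summed and maximal overhangs maximised — the MO of the
    pooled read set is the maximum over the subsets.
    """
    merged: dict[tuple, Junction] = {}
    for j in junctions:
        key = (j.chrom, j.start, j.end, j.strand)
        if key in merged:
            prev = merged[key]
            merged[key] = Junction(
                chrom=j.chrom, start=j.start, end=j.end, strand=j.strand,
                mol=max(prev.mol, j.mol), mor=max(prev.mor, j.mor),
                support=prev.support + j.support, name=prev.name,
            )
        else:
            merged[key] = j
    return sorted(merged.values(), key=lambda j: (j.chrom, j.start, j.end))


def filter_support(junctions: Iterable[Junction], min_reads: int = 3) -> list[Junction]:
    """Keep junctions supported by at least ``min_reads`` reads."""
    return [j for j in junctions if j.support >= min_reads]


# ---------------------------------------------------------------------------
# classification


def block_exon_hits(
    block: GenomicInterval, ann: AnnotationIndex, strict_boundary: str | None = None
) -> list[ExonHit]:
    """All (gene, transcript, exon) records overlapping ``block`` by >= 1 bp.

    ``strict_boundary`` (``"left"``/``"right"``) additionally requires the
    block's intron-proximal edge to coincide with the exon boundary: a
    left anchor must end exactly at an exon end, a right anchor must
    start exactly at an exon start.
    """
    hits: list[ExonHit] = []
    tree = ann.exon_tree(block.chrom)
    gidx_cache: dict[str, dict[int, int]] = {}
    for node in tree.overlap(block.start, block.end):
        exon: Exon = node.data
        if strict_boundary == "left" and exon.interval.end != block.end:
            continue
        if strict_boundary == "right" and exon.interval.start != block.start:
            continue
        tx = ann.genes[exon.gene_id].transcripts[exon.transcript_id]
        if exon.transcript_id not in gidx_cache:
            gidx_cache[exon.transcript_id] = {
                e.rank: i for i, e in enumerate(tx.exons)
            }
        hits.append(
            ExonHit(
                gene_id=exon.gene_id,
                transcript_id=exon.transcript_id,
                rank=exon.rank,
                genomic_index=gidx_cache[exon.transcript_id][exon.rank],
                exon=exon.interval,
                overlap=block.overlap_length(exon.interval),
            )
        )
    hits.sort(key=lambda h: (h.gene_id, h.transcript_id, h.genomic_index))
    return hits


def classify_junction(
    junction: Junction, ann: AnnotationIndex, strict: bool = False
) -> JunctionCall:
    """Assign the first satisfied category in the 1..7 hierarchy."""
    hits_l = block_exon_hits(
        junction.left_block, ann, strict_boundary="left" if strict else None
    )
    hits_r = block_exon_hits(
        junction.right_block, ann, strict_boundary="right" if strict else None
    )

    by_tx_l: dict[str, list[ExonHit]] = {}
    by_tx_r: dict[str, list[ExonHit]] = {}
    for h in hits_l:
        by_tx_l.setdefault(h.transcript_id, []).append(h)
    for h in hits_r:
        by_tx_r.setdefault(h.transcript_id, []).append(h)

    def _strand_note(hits: Sequence[ExonHit]) -> list[str]:
        if junction.strand == ".":
            return []
        out = []
        for h in hits:
            tx_strand = ann.genes[h.gene_id].transcripts[h.transcript_id].strand
            if tx_strand != junction.strand:
                out.append(h.transcript_id)
        return sorted(set(out))

    # 1 annotated / 2 exon skipping: both blocks in exons of one transcript
    skip_evidence = None
    for tid in by_tx_l:
        if tid not in by_tx_r:
            continue
        for hl in by_tx_l[tid]:
            for hr in by_tx_r[tid]:
                if hl.genomic_index == hr.genomic_index:
                    continue  # same exon: handled by category 4
                gap = hr.genomic_index - hl.genomic_index
                if gap == 1:
                    return JunctionCall(
                        junction, 1,
                        {
                            "transcript_id": tid,
                            "gene_id": hl.gene_id,
                            "left_exon_rank": hl.rank,
                            "right_exon_rank": hr.rank,
                            "strand_mismatch": _strand_note([hl, hr]),
                        },
                    )
                if gap >= 2 and skip_evidence is None:
                    skip_evidence = {
                        "transcript_id": tid,
                        "gene_id": hl.gene_id,
                        "left_exon_rank": hl.rank,
                        "right_exon_rank": hr.rank,
                        "skipped_exons": gap - 1,
                        "strand_mismatch": _strand_note([hl, hr]),
                    }
    if skip_evidence is not None:
        return JunctionCall(junction, 2, skip_evidence)

    # 3 only one side
    if bool(hits_l) != bool(hits_r):
        side = "left" if hits_l else "right"
        hits = hits_l or hits_r
        return JunctionCall(
            junction, 3,
            {
                "mapped_side": side,
                "transcript_ids": sorted({h.transcript_id for h in hits}),
                "gene_ids": sorted({h.gene_id for h in hits}),
                "strand_mismatch": _strand_note(hits),
            },
        )

    # 4 intra-exonic: both blocks within the same single exon
    if hits_l and hits_r:
        shared = {
            (h.transcript_id, h.genomic_index) for h in hits_l
        } & {(h.transcript_id, h.genomic_index) for h in hits_r}
        if shared:
            tid, gidx = sorted(shared)[0]
            hit = next(
                h for h in hits_l
                if h.transcript_id == tid and h.genomic_index == gidx
            )
            return JunctionCall(
                junction, 4,
                {
                    "transcript_id": tid,
                    "gene_id": hit.gene_id,
                    "exon_rank": hit.rank,
                    "strand_mismatch": _strand_note([hit]),
                },
            )

        # 5 different transcripts of the same gene
        genes_l = {h.gene_id for h in hits_l}
        genes_r = {h.gene_id for h in hits_r}
        common = genes_l & genes_r
        if common:
            gid = sorted(common)[0]
            tl = sorted({h.transcript_id for h in hits_l if h.gene_id == gid})
            tr = sorted({h.transcript_id for h in hits_r if h.gene_id == gid})
            return JunctionCall(
                junction, 5,
                {
                    "gene_id": gid,
                    "left_transcripts": tl,
                    "right_transcripts": tr,
                    "strand_mismatch": _strand_note(hits_l + hits_r),
                },
            )

        # 6 trans-splicing: exons of two different genes
        adjacency = _genes_adjacent(ann, sorted(genes_l)[0], sorted(genes_r)[0])
        return JunctionCall(
            junction, 6,
            {
                "left_genes": sorted(genes_l),
                "right_genes": sorted(genes_r),
                "adjacent": adjacency,
                "strand_mismatch": _strand_note(hits_l + hits_r),
            },
        )

    # 7 intronic/intergenic: no exon on either side
    return JunctionCall(junction, 7, {})


def _genes_adjacent(ann: AnnotationIndex, gid_a: str, gid_b: str) -> bool:
    """True when no third gene span lies between the two gene spans."""
    a, b = ann.genes[gid_a].span, ann.genes[gid_b].span
    if a.chrom != b.chrom:
        return False
    lo, hi = min(a.end, b.end), max(a.start, b.start)
    if lo >= hi:
        return True  # overlapping spans
    for gene in ann.genes.values():
        if gene.gene_id in (gid_a, gid_b):
            continue
        span = gene.span
        if span.chrom == a.chrom and span.start < hi and span.end > lo:
            return False
    return True


def classify_all(
    junctions: Iterable[Junction], ann: AnnotationIndex, strict: bool = False
) -> tuple[list[JunctionCall], pd.DataFrame]:
    """Classify every junction and summarise counts per gene and category.

    The summary attributes each call to the gene symbols appearing in its
    evidence (category 7 calls, which touch no gene, are tallied under
    ``.``). Categories 2-7 are evidence of unannotated isoforms or loci
    and are flagged ``novel``.
    """
    calls = [classify_junction(j, ann, strict=strict) for j in junctions]
    rows = []
    for call in calls:
        gene_ids = _evidence_genes(call)
        symbols = sorted(
            {ann.genes[g].name for g in gene_ids if g in ann.genes}
        ) or ["."]
        for symbol in symbols:
            rows.append(
                {
                    "gene": symbol,
                    "category": call.category,
                    "category_name": call.category_name,
                    "novel": call.category >= 2,
                }
            )
    if rows:
        summary = (
            pd.DataFrame(rows)
            .groupby(["gene", "category", "category_name", "novel"])
            .size()
            .reset_index(name="n_junctions")
            .sort_values(["gene", "category"])
            .reset_index(drop=True)
        )
    else:
        summary = pd.DataFrame(
            columns=["gene", "category", "category_name", "novel", "n_junctions"]
        )
    return calls, summary


def _evidence_genes(call: JunctionCall) -> list[str]:
    ev = call.evidence
    genes: list[str] = []
    for key in ("gene_id",):
        if key in ev:
            genes.append(ev[key])
    for key in ("gene_ids", "left_genes", "right_genes"):
        genes.extend(ev.get(key, []))
    return sorted(set(genes))


def calls_to_dataframe(calls: list[JunctionCall]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(calls, 1):
        j = c.junction
        rows.append(
            {
                "junction_id": j.name or f"JUNC{i:05d}",
                "chrom": j.chrom,
                "start": j.start,
                "end": j.end,
                "strand": j.strand,
                "support": j.support,
                "mol": j.mol,
                "mor": j.mor,
                "category": c.category,
                "category_name": c.category_name,
                "evidence": ";".join(f"{k}={v}" for k, v in sorted(c.evidence.items())),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id", "chrom", "start", "end", "strand", "support",
            "mol", "mor", "category", "category_name", "evidence",
        ],
    )
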