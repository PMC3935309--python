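"""Shared fixtures: a toy two-gene annotation and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from novotx.intervals import GenomicInterval
from novotx.regions import AnnotationIndex, Exon, Gene, Transcript


def build_annotation(genes_spec, chrom_sizes):
    """Build an AnnotationIndex from nested literals.

    ``genes_spec`` maps gene_id -> (strand, {transcript_id: [(start, end), ...]}).
    """
    genes = {}
    for gid, (strand, txs) in genes_spec.items():
        gene = Gene(gene_id=gid, name=gid, strand=strand)
        for tid, exon_coords in txs.items():
            tx = Transcript(transcript_id=tid, gene_id=gid, strand=strand)
            ordered = sorted(exon_coords)
            n = len(ordered)
            for k, (s, e) in enumerate(ordered):
                rank = k + 1 if strand != "-" else n - k
                tx.exons.append(
                    Exon(gid, tid, rank, GenomicInterval("chrT", s, e, strand))
                )
            gene.transcripts[tid] = tx
        genes[gid] = gene
    return AnnotationIndex(genes, chrom_sizes)


@pytest.fixture
def toy_annotation():
    """Gene G1 (T1: exons [0,100), [200,300), [400,500)); G2 (T2: [1000,1100))."""
    return build_annotation(
        {
            "G1": ("+", {"T1": [(0, 100), (200, 300), (400, 500)]}),
            "G2": ("+", {"T2": [(1000, 1100)]}),
        },
        {"chrT": 2000},
    )


def brute_force_compartments(ann, chrom, size):
    """Per-base membership over a small chromosome.

    Returns (intronic_mask, intergenic_mask, genic_mask) boolean arrays.
    A base is genic iff inside some gene span, intronic iff inside some
    transcript span and no exon, intergenic iff in no gene span.
    """
    in_gene = np.zeros(size, dtype=bool)
    in_tx = np.zeros(size, dtype=bool)
    in_exon = np.zeros(size, dtype=bool)
    for gene in ann.genes.values():
        if gene.chrom != chrom:
            continue
        span = gene.span
        in_gene[span.start:span.end] = True
        for tx in gene.transcripts.values():
            tspan = tx.span
            in_tx[tspan.start:tspan.end] = True
            for exon in tx.exons:
                in_exon[exon.interval.start:exon.interval.end] = True
    return in_tx & ~in_exon, ~in_gene, in_gene


def mask_from_intervals(ivs, chrom, size):
    mask = np.zeros(size, dtype=bool)
    for iv in ivs:
        if iv.chrom == chrom:
            mask[iv.start:iv.end] = True
    return mask


def bh_step_up_oracle(pvalues):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for pos_i, idx in enumerate(order):
        best = min(
            pvalues[order[pos_j]] * m / (pos_j + 1)
            for pos_j in range(pos_i, m)
        )
        q[idx] = min(1.0, best)
    return q


def poisson_sf_oracle(k, mu):
    """P(X >= k) by direct pmf summation of the complement."""
    if k == 0:
        return 1.0
    term = np.exp(-mu)  # pmf(0)
    cdf = term
    for i in range(1, k):
        term *= mu / i
        cdf += term
    return max(0.0, 1.0 - cdf)


def random_toy_annotation(rng, size=10_000, max_genes=3):
    """A random small annotation for oracle comparisons."""
    genes_spec = {}
    cursor = int(rng.integers(0, 200))
    for gi in range(int(rng.integers(1, max_genes + 1))):
        n_tx = int(rng.integers(1, 3))
        strand = "+" if rng.random() < 0.5 else "-"
        txs = {}
        gene_start = cursor
        gene_end = cursor
        for ti in range(n_tx):
            n_exons = int(rng.integers(1, 5))
            exons = []
            pos = gene_start + int(rng.integers(0, 100))
            for _ in range(n_exons):
                elen = int(rng.integers(20, 200))
                if pos + elen >= size:
                    break
                exons.append((pos, pos + elen))
                pos += elen + int(rng.integers(30, 400))
            if not exons:
                exons = [(gene_start, gene_start + 20)]
            txs[f"G{gi}T{ti}"] = exons
            gene_end = max(gene_end, exons[-1][1])
        genes_spec[f"G{gi}"] = (strand, txs)
        cursor = gene_end + int(rng.integers(100, 600))
        if cursor >= size - 300:
            break
    return build_annotation(genes_spec, {"chrT": size})
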