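"""High-coverage-peak (HCP) calling.

The model: within each compartment (intronic, intergenic) read starts
are assumed to fall as a homogeneous Poisson process with unknown per-bp
intensity lambda. Lambda is estimated by maximum likelihood on
background-eligible regions — long intervals far from gene/exon
boundaries, where no annotated signal is expected — which for a
homogeneous Poisson process is simply (reads observed) / (bp scanned).
Each window of true width w is then tested against its expected count
mu = lambda * w with an upper-tail Poisson test P(X >= k); p-values are
Benjamini-Hochberg adjusted separately within each compartment (each has
its own independently-estimated rate, hence its own test family), and
windows with q <= fdr are merged into HCPs whenever the gap between
consecutive significant windows is at most one nominal window width.

A flank scan reports, per transcript, read counts and Poisson p-values
in windows of a ladder of widths placed immediately upstream of the TSS
and downstream of the transcript end (strand-aware), using the
intergenic rate; it is a coverage assessment, not a multiple-testing
family, so no FDR adjustment is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import count_reads_in_windows, _as_start_arrays
from .intervals import GenomicInterval, merge_intervals, total_length
from .regions import (
    AnnotationIndex,
    CompartmentSet,
    Window,
    derive_compartments,
    make_windows,
    select_background_regions,
)

log = logging.getLogger(__name__)

FLANK_WIDTHS: tuple[int, ...] = (50, 100, 200, 500, 1000)


class EmptyBackgroundError(ValueError):
    """No background-eligible bases; relax thresholds or use the fallback."""


@dataclass
class BackgroundModel:
    """Per-compartment Poisson intensities (reads per bp) and provenance."""

    lambda_intronic: float
    lambda_intergenic: float
    summary: dict = field(default_factory=dict)

    def rate(self, compartment: str) -> float:
        if compartment == "intronic":
            return self.lambda_intronic
        if compartment in ("intergenic", "flank"):
            return self.lambda_intergenic
        raise KeyError(f"no rate for compartment {compartment!r}")


@dataclass
class HCP:
    """A merged run of significant windows: a candidate transcribed region."""

    chrom: str
    start: int
    end: int
    compartment: str
    n_windows: int
    total_reads: int
    min_q: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# statistics


def estimate_lambda(reads, background: Sequence[GenomicInterval]) -> tuple[float, int, int]:
    """Maximum-likelihood per-bp rate over background regions.

    For a homogeneous Poisson process the MLE is the sample mean:
    (number of read starts inside the background) / (background bp).
    Returns ``(rate, n_reads, n_bp)``. Raises
    :class:`EmptyBackgroundError` when the background is empty.
    """
    background = merge_intervals(background)
    n_bp = total_length(background)
    if n_bp == 0:
        raise EmptyBackgroundError(
            "background region set is empty; lower the min-length thresholds "
            "or enable the whole-compartment fallback"
        )
    starts = _as_start_arrays(reads)
    n_reads = 0
    for iv in background:
        arr = starts.get(iv.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, iv.start, side="left")
        hi = np.searchsorted(arr, iv.end, side="left")
        n_reads += int(hi - lo)
    return n_reads / n_bp, n_reads, n_bp


def poisson_upper_tail(k: int, mu: float) -> float:
    """Upper-tail Poisson probability P(X >= k) for X ~ Poisson(mu).

    Equals 1 for k = 0. ``mu`` must be positive.
    """
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    k = int(k)
    if k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    if k == 0:
        return 1.0
    # survival function at k-1: P(X > k-1) = P(X >= k)
    return float(stats.poisson.sf(k - 1, mu))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of (p_(j) * m / j), capped at 1, returned in
    the input order. Empty input yields an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# window-level calling


def call_windows(
    windows: list[Window],
    model: BackgroundModel,
    fdr: float = 0.05,
    pooled: bool = False,
) -> list[Window]:
    """Attach mu, p, q and the significance flag to counted windows.

    BH is applied separately within each compartment family by default
    (each compartment has its own rate); ``pooled=True`` corrects across
    all windows as one family.
    """
    for w in windows:
        lam = model.rate(w.compartment)
        w.mu = lam * w.width
        w.p = poisson_upper_tail(w.count, w.mu)
    families: dict[str, list[Window]]
    if pooled:
        families = {"all": list(windows)}
    else:
        families = {}
        for w in windows:
            families.setdefault(w.compartment, []).append(w)
    for fam in families.values():
        q = bh_adjust([w.p for w in fam])
        for w, qv in zip(fam, q.tolist()):
            w.q = qv
            w.significant = qv <= fdr
    return windows


def merge_significant(windows: list[Window]) -> list[HCP]:
    """Merge significant windows into HCPs.

    Within a compartment, consecutive significant windows are merged
    whenever the gap between them is at most one nominal window width.
    """
    hcps: list[HCP] = []
    by_comp: dict[str, list[Window]] = {}
    for w in windows:
        if w.significant:
            by_comp.setdefault(w.compartment, []).append(w)
    for comp, sig in by_comp.items():
        sig.sort(key=lambda w: (w.chrom, w.start))
        run: list[Window] = []
        for w in sig:
            if run and (
                w.chrom != run[-1].chrom
                or w.start - run[-1].end > run[-1].nominal_width
            ):
                hcps.append(_close_run(run, comp))
                run = []
            run.append(w)
        if run:
            hcps.append(_close_run(run, comp))
    hcps.sort(key=lambda h: (h.chrom, h.start))
    return hcps


def _close_run(run: list[Window], compartment: str) -> HCP:
    return HCP(
        chrom=run[0].chrom,
        start=run[0].start,
        end=run[-1].end,
        compartment=compartment,
        n_windows=len(run),
        total_reads=sum(w.count for w in run),
        min_q=min(w.q for w in run),
    )


# ---------------------------------------------------------------------------
# background estimation with fallback


def estimate_background(
    reads,
    comp: CompartmentSet,
    intergenic_min_len: int = 1_000_000,
    intergenic_trim: int = 10_000,
    intronic_min_len: int = 300_000,
    intronic_trim: int = 1_000,
    allow_fallback: bool = True,
) -> BackgroundModel:
    """Estimate lambda_intronic and lambda_intergenic.

    The primary estimate uses background-eligible regions (long intervals
    trimmed away from boundaries). When a compartment yields no eligible
    region — common on small genomes — and ``allow_fallback`` is true,
    the rate is instead estimated on the whole compartment with each
    interval shrunk by the same boundary trim (intervals too short to
    trim are used untrimmed); this is logged. A compartment with zero
    background reads receives a pseudocount of one read over its span so
    p-values stay defined.
    """
    reads = _as_start_arrays(reads)
    intronic_bg, intergenic_bg = select_background_regions(
        comp,
        intergenic_min_len=intergenic_min_len,
        intergenic_trim=intergenic_trim,
        intronic_min_len=intronic_min_len,
        intronic_trim=intronic_trim,
    )
    summary: dict = {}
    rates: dict[str, float] = {}
    for name, bg, full, trim in (
        ("intronic", intronic_bg, comp.intronic, intronic_trim),
        ("intergenic", intergenic_bg, comp.intergenic, intergenic_trim),
    ):
        used = bg
        fallback = False
        if total_length(used) == 0:
            if not allow_fallback:
                raise EmptyBackgroundError(
                    f"no background-eligible {name} regions and fallback disabled"
                )
            used = [
                GenomicInterval(iv.chrom, iv.start + trim, iv.end - trim)
                if iv.length > 2 * trim
                else iv
                for iv in full
            ]
            fallback = True
            log.info(
                "no background-eligible %s regions; falling back to the "
                "whole compartment (trim %d bp)", name, trim,
            )
        if total_length(used) == 0:
            raise EmptyBackgroundError(f"{name} compartment is empty")
        rate, n_reads, n_bp = estimate_lambda(reads, used)
        pseudocount = False
        if n_reads == 0:
            rate = 1.0 / n_bp
            pseudocount = True
            log.warning(
                "zero background reads in %s; applying pseudocount 1/%d bp",
                name, n_bp,
            )
        rates[name] = rate
        summary[name] = {
            "reads": n_reads,
            "bp": n_bp,
            "fallback": fallback,
            "pseudocount": pseudocount,
        }
    return BackgroundModel(
        lambda_intronic=rates["intronic"],
        lambda_intergenic=rates["intergenic"],
        summary=summary,
    )


# ---------------------------------------------------------------------------
# flank scan


def scan_flanks(
    ann: AnnotationIndex,
    reads,
    model: BackgroundModel,
    widths: Iterable[int] = FLANK_WIDTHS,
) -> pd.DataFrame:
    """Coverage assessment upstream of TSSs and downstream of transcript ends.

    For each transcript and each width, one window is placed immediately
    upstream of the TSS and one immediately downstream of the transcript
    end (strand-aware: upstream of a minus-strand transcript extends to
    larger coordinates). Expected counts use the intergenic rate. Windows
    overlapping any annotated exon are flagged; windows truncated at a
    chromosome edge keep their true (rescaled) width and are flagged.
    """
    reads = _as_start_arrays(reads)
    widths = sorted(set(int(w) for w in widths))
    rows = []
    windows: list[Window] = []
    meta: list[dict] = []
    for tx in ann.transcripts():
        span = tx.span
        size = ann.chrom_sizes.get(tx.chrom)
        for width in widths:
            if tx.strand == "-":
                flank_defs = [
                    ("upstream", span.end, span.end + width),
                    ("downstream", span.start - width, span.start),
                ]
            else:
                flank_defs = [
                    ("upstream", span.start - width, span.start),
                    ("downstream", span.end, span.end + width),
                ]
            for side, start, end in flank_defs:
                truncated = False
                if start < 0:
                    start, truncated = 0, True
                if size is not None and end > size:
                    end, truncated = size, True
                if start >= end:
                    continue
                w = Window(tx.chrom, start, end, compartment="flank",
                           nominal_width=width)
                windows.append(w)
                meta.append(
                    {
                        "transcript_id": tx.transcript_id,
                        "gene_id": tx.gene_id,
                        "strand": tx.strand,
                        "side": side,
                        "nominal_width": width,
                        "truncated": truncated,
                    }
                )
    count_reads_in_windows(reads, windows)
    for w, m in zip(windows, meta):
        mu = model.lambda_intergenic * w.width
        p = poisson_upper_tail(w.count, mu) if mu > 0 else 1.0
        tree = ann.exon_tree(w.chrom)
        exon_overlap = bool(tree.overlap(w.start, w.end))
        rows.append(
            {
                **m,
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "width": w.width,
                "count": w.count,
                "mu": mu,
                "p": p,
                "exon_overlap": exon_overlap,
            }
        )
    columns = [
        "transcript_id", "gene_id", "strand", "side", "nominal_width",
        "chrom", "start", "end", "width", "count", "mu", "p",
        "exon_overlap", "truncated",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class HCPResult:
    windows: list[Window]
    model: BackgroundModel
    hcps: list[HCP]
    compartments: CompartmentSet


def call_hcps(
    ann: AnnotationIndex,
    reads,
    intronic_window: int = 200,
    intergenic_window: int = 500,
    fdr: float = 0.05,
    intergenic_min_len: int = 1_000_000,
    intergenic_trim: int = 10_000,
    intronic_min_len: int = 300_000,
    intronic_trim: int = 1_000,
    pooled_fdr: bool = False,
    counting_mode: str = "start",
) -> HCPResult:
    """Run the full discovery pipeline on an annotation and read set."""
    reads = _as_start_arrays(reads) if counting_mode == "start" else list(reads)
    comp = derive_compartments(ann)
    windows = make_windows(comp.intronic, intronic_window, "intronic")
    windows += make_windows(comp.intergenic, intergenic_window, "intergenic")
    count_reads_in_windows(reads, windows, mode=counting_mode)
    model = estimate_background(
        reads if counting_mode == "start" else _as_start_arrays(reads),
        comp,
        intergenic_min_len=intergenic_min_len,
        intergenic_trim=intergenic_trim,
        intronic_min_len=intronic_min_len,
        intronic_trim=intronic_trim,
    )
    call_windows(windows, model, fdr=fdr, pooled=pooled_fdr)
    hcps = merge_significant(windows)
    return HCPResult(windows=windows, model=model, hcps=hcps, compartments=comp)


# ---------------------------------------------------------------------------
# writers


def windows_to_dataframe(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "compartment": [w.compartment for w in windows],
            "width": [w.width for w in windows],
            "count": [w.count for w in windows],
            "mu": [w.mu for w in windows],
            "p": [w.p for w in windows],
            "q": [w.q for w in windows],
            "significant": [w.significant for w in windows],
        }
    )


def write_hcp_bed(hcps: list[HCP], path) -> None:
    """BED6: name = HCP id, score = -10*log10(min q) capped at 1000."""
    with open(path, "w") as fh:
        for i, h in enumerate(hcps, 1):
            if h.min_q > 0:
                score = min(1000, int(round(-10 * np.log10(h.min_q))))
            else:
                score = 1000
            score = max(0, score)
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\tHCP_{i:05d}_{h.compartment}"
                f"\t{score}\t.\n"
            )
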