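# Methods

## Problem

Bulk (or pooled single-cell) RNA-seq of a well-annotated genome still
produces reads that map outside annotated exons. Two signals of
unannotated transcription are extracted here from the mapped reads of a
single sample:

1. **High coverage peaks (HCPs)** — runs of intronic or intergenic
   windows whose read counts exceed a Poisson background, candidate
   unannotated exons or transcripts;
2. **Novel splice junctions** — spliced alignments whose two exonic
   anchors do not correspond to a known consecutive-exon pair, evidence
   of unannotated isoforms (alternative splicing), intra-exonic splicing
   or trans-splicing.

## HCP model

Compartments are derived from the annotation with conservative,
novelty-oriented definitions. A base is *intronic* iff it lies inside at
least one transcript span and inside no exon of **any** transcript of any
gene; a base is *intergenic* iff it lies inside no gene span. Both
compartments therefore exclude every annotated exon base, and
`genic ∪ intergenic` tiles each chromosome exactly once.

Within a compartment, read **starts** are modelled as a homogeneous
Poisson process with per-bp intensity λ. Each compartment's λ is
estimated by maximum likelihood — for a homogeneous Poisson process this
is simply `reads observed / bp scanned` — on *background-eligible*
regions: intergenic intervals longer than 1 Mb with 10 kb trimmed from
each end (distance from gene boundaries), and intronic intervals longer
than 300 kb with 1 kb trimmed from each end (distance from exon
boundaries). Eligibility is judged on the untrimmed interval length and
the thresholds are strict (`>`, not `≥`).

Compartments are tiled left-to-right into windows of 200 bp (intronic)
and 500 bp (intergenic); a trailing partial tile is kept with its true
width. Each window of true width *w* and count *k* is tested against
μ = λ·w with the upper-tail Poisson probability P(X ≥ k), which is 1 at
k = 0. Working with a per-bp rate rather than a per-window mean lets one
model serve both window widths and partial tiles.

P-values are Benjamini–Hochberg step-up adjusted
(q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, capped at 1) **separately within each
compartment** — each compartment has its own independently-estimated λ,
so intronic and intergenic windows form two test families (a pooled mode
is available). Windows with q ≤ 0.05 (configurable) are significant, and
consecutive significant windows of a compartment merge into one HCP
whenever the gap between them is at most one nominal window width. Each
HCP reports its merged span, member-window count, total reads and the
minimum q over members.

A **flank scan** assesses transcription immediately upstream of each
TSS and downstream of each transcript end with a ladder of window widths
{50, 100, 200, 500, 1000} bp, strand-aware (upstream of a minus-strand
transcript extends toward larger coordinates), using the intergenic λ.
It is reported as a coverage assessment without FDR adjustment (a config
option can fold the flanks into the intergenic BH family); windows
overlapping any annotated exon, or truncated at a chromosome edge, are
flagged.

### Parameters

| parameter | default | unit | role |
|---|---|---|---|
| intronic window | 200 | bp | tile width in introns |
| intergenic window | 500 | bp | tile width between genes |
| FDR threshold | 0.05 | q-value | window significance |
| intergenic background | >1 Mb, 10 kb trim | bp | λ_intergenic estimation |
| intronic background | >300 kb, 1 kb trim | bp | λ_intronic estimation |
| min junction reads | 3 | reads | junction support filter |

The FDR cutoff and the per-compartment (vs pooled) BH family structure
are package choices exposed as configuration; the window widths,
background-region thresholds and the ≥3-read junction filter are the
method's published constants and are echoed verbatim in every run's
`resolved_config.txt`.

### Numerical and degenerate-input choices

* The upper tail is computed as `scipy.stats.poisson.sf(k-1, μ)`; tests
  pin agreement with direct pmf summation to 1e-10 over k ≤ 200, μ ≤ 50.
* **Zero-read background**: λ = 0 makes every p-value undefined, so a
  pseudocount of one read over the background span is applied and a
  warning logged.
* **Small genomes**: toy chromosomes rarely contain a >1 Mb intergenic
  interval. When a compartment yields no background-eligible region the
  estimator falls back to the whole compartment with the same boundary
  trim applied to each interval (intervals too short to trim are used
  untrimmed), and logs that it did so. Defaults always reproduce the
  published thresholds first.
* Counting assigns each read to the unique window containing its start
  (no double counting; an any-overlap mode exists as a switch).
  Read length is therefore irrelevant to counting.
* Ties in BH are handled by stable sorting; the adjustment is
  order-invariant by construction.

## Junction classification

A junction *j* spans `[S, E)` with left and right anchor blocks
`L = [S, S+MOL)` and `R = [E−MOR, E)`, where MOL/MOR are the maximal
overhangs over all reads supporting the junction — exactly the TopHat
`junctions.bed` encoding (BED12, two blocks, score = supporting reads).
Records with other block counts, or whose blocks overlap, are rejected
with a warning; duplicate records (same chrom/S/E/strand) are merged
with supports summed and overhangs maximised before the ≥3-read support
filter.

Each block is intersected with all annotated exons; "maps to an exon"
means ≥1 bp overlap (intersectBed default semantics, strand-blind). A
strict mode additionally requires the block's intron-proximal edge to
coincide with the exon boundary. Categories are tested in a fixed order
and the first satisfied wins:

1. **annotated** — some transcript holds L and R in consecutive exons
   (adjacent in genomic order, which equals transcription-order
   adjacency on either strand);
2. **exon skipping** — some transcript holds L and R in exons with rank
   gap ≥ 2 (same-exon pairs are excluded);
3. **only one side** — exactly one block overlaps any exon;
4. **intra-exonic** — both blocks overlap the same single exon;
5. **different transcripts** — L and R hit exons of two different
   transcripts of one gene, and (implied by the hierarchy) no single
   transcript holds both;
6. **trans-splicing** — L and R hit exons of different genes; gene
   adjacency is reported in the evidence but not required;
7. **intronic/intergenic** — neither block hits any exon.

The order makes the categories mutually exclusive and exhaustive; a
junction annotated in one isoform but skipping in another is category 1.
A junction strand disagreeing with the matched transcript's strand is
reported in the evidence, never used to veto the match. Per-gene
summaries count junctions per category per gene symbol; categories 2–7
flag evidence of unannotated isoforms or loci.

## Synthetic data

The generator emulates the workflow's inputs at desk scale: one small
chromosome (default 2 Mb) with six non-overlapping genes (3–5 exons,
150–400 bp; introns 3–12 kb; 1–2 isoforms, the alternative isoform
skipping one internal exon and adding a private intronic exon so that
isoform-exclusive exons exist), uniform background read starts at
0.01 reads/bp — the mapped-read density of a single-chromosome slice of
a typical bulk library — a 20× elevated rate over exons, twenty planted
regions at 10× background spanning 3–10 windows (aligned to the window
grid, kept ≥1 window from compartment edges and ≥2 windows apart), and
one constructed junction per category with supports drawn in [3, 50].
Reads are written as 50 bp sorted BED; junctions in the TopHat dialect;
planted truth as TSV. The same seed gives byte-identical files.

Not emulated: sequencing error, mappability, GC/positional coverage
bias, fragment-length structure, overlapping genes (optional), and real
exon/intron length distributions. Passing closed-loop tests therefore
demonstrates correctness of the statistics and interval logic under the
stated model, not robustness to real-library artefacts such as
mappability holes or clonal duplicates.

## Problem sizes used in tests and the acceptance script

Null calibration uses a 2 Mb single-compartment simulation tiled into
10,000 × 200 bp windows at 0.002 reads/bp, with 20 replicates for the
false-discovery count; recovery uses the generator defaults above;
classifier exactness uses 7 categories × 10 seeds on a 600 kb
three-gene genome; interval-algebra oracles use 50 random ≤10 kb toy
genomes checked per base. The whole suite runs in well under a minute on
one CPU.

## Known limitations

* A single λ per compartment: no local background (no sliding-window
  λ as in full MACS-style peak callers), so regional mappability or
  copy-number variation can create false HCPs on real data.
* Start-coordinate counting slightly under-weights windows relative to
  any-overlap counting near boundaries; the switch exists because the
  original convention is not documented.
* The flank scan's width ladder is a fixed set; nested/adaptive
  schemes are not implemented.
* BED12 annotation input carries no gene grouping, so each record is
  its own single-transcript gene; category-5 calls require GTF input.
* Junction classification is strand-blind by design; antisense
  junctions over an annotated gene classify against its exons.
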