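# Methods

`asval` validates structural variants (SVs) from nanopore adaptive-sampling
runs. Adaptive sampling is in-silico target enrichment: the sequencer
compares the first few hundred bases of each molecule against a reference
of targeted regions and either lets the molecule finish (accepted,
"on-target") or ejects it from the pore (rejected, "off-target"). The
result is a characteristic two-class run: long reads at high depth over
the targets, and short ejected reads (~0.5 kb) tiling the whole genome
thinly. The package turns both classes into evidence about rearrangements:
read depth for copy number, split alignments for breakpoint junctions, and
the combination for full rearrangement architectures.

## Read classes and quality filtering

A read is off-target exactly when its MinKNOW `end_reason` equals
`data_service_unblock_mux_change`; every other end reason counts as
on-target. The partition is total. Reads with mean quality below Q10 are
discarded before any depth arithmetic; a read at exactly Q10 is kept
(the filter is strict-below). Run statistics follow the field's usual
definitions: N50 is the largest length L such that reads of length ≥ L
contain at least half of all bases; per-region depth is aligned bases in
the region divided by region length, using all passing reads regardless
of fate (stray ejected reads inside a target still count); enrichment is
mean autosomal on-target depth over mean genome-wide depth. On male
samples, chrX regions are excluded from the autosomal mean (one X copy);
sample sex is a configuration input, never inferred.

## Copy number over targets

Depth is computed in 500 bp bins (mean depth: aligned bases overlapping
the bin / bin width, alignments clipped at bin edges — the same quantity
mosdepth reports). Each bin is expressed as a log2 ratio r against the
length-weighted mean depth mu over **all** target bins in the sample.
This within-sample, across-targets normalization is the key trick for
targeted runs: there is no genome-wide baseline, and a region's own
flanks may themselves be rearranged, so only the external targets can
anchor the diploid level. On male samples chrX bins are excluded from mu
and ratioed against mu/2, so a normal hemizygous X sits at r = 0 with
copy-number baseline 1. Expected levels on autosomes: −1 for a
heterozygous deletion (CN 1), +0.585 for a single-copy gain (CN 3),
+1.585 for CN 6. Zero-depth bins are floored at r = −5 rather than −inf.

No separate treatment of the ejected-read contribution is needed: stray
ejected reads inside a CNV scale with the local copy number exactly like
accepted reads (both sample the same genome), so the plain ratio is
already an unbiased copy-number ratio.

### Segmentation

Bins are grouped into non-overlapping windows of 10 bins (5 kb,
configurable). Windowed thresholding classifies a window as loss at
r ≤ −0.415, gain at r ≥ +0.32 (values exactly at a cut count as
aberrant); the cut-offs are symmetric in copy-number space around the
midpoints toward CN 1.5 and CN 2.5 and are configurable.

Two refinements make the windowed calls robust:

1. **Recentering.** The all-targets mean is biased upward when a
   rearranged locus is a non-trivial fraction of the targeted material
   (its extra copies inflate the mean). The reference is therefore
   re-estimated from the windows classified neutral (up to three
   iterations), pinning copy-neutral windows at r = 0 regardless of
   target composition. In a clinical-scale run (~36 Mb of targets,
   sub-Mb events) the effect is negligible; on desk-scale fixtures it is
   not.
2. **Penalized partitioning with quantized boundary polish.** Merging
   windows by status alone cannot separate distinct gain plateaus (a
   triplicated flank and a quintuplicated core are both "gain"). Window
   means are instead fit per region with a piecewise-constant model by
   optimal partitioning: within-segment squared error plus an L0 penalty
   per boundary, beta = 28 · sigma² · ln n, with sigma estimated robustly
   (scaled MAD of adjacent-window differences, insensitive to genuine
   steps) and segments at least `min_windows` = 3 windows long. The
   penalty multiplier is far above the BIC's 2 because window noise is
   correlated over roughly a read length and compound-Poisson coverage
   produces occasional sustained excursions; 28 keeps those excursions
   below the penalty while one-copy steps over plateaus of a few windows
   clear it by an order of magnitude. Fitted pieces are classified by
   the cut-offs, adjacent pieces with equal status and integer CN merge,
   and each boundary between different-CN segments is finally re-placed
   within ±5 windows to minimize the squared distance of each window to
   its side's *fixed* expected level log2(cn/baseline) — the quantized
   model resolves the cases where an unconstrained fit attaches a short
   noise excursion to the wrong side.

Integer copy number is cn = round(baseline · 2^r) with baseline 2
(autosomes, female X) or 1 (male X); for a segment whose thresholded
status is aberrant, cn is additionally pushed at least one copy away
from baseline so status and integer estimate never contradict each
other at the cut boundary. At 28x with 12 kb reads the caller still
emits occasional short (3–5 window) aberrant segments at the cut-offs —
an inherent property of thresholding Poisson depth; consumers filter by
length or rely on the planted-event statistics, which are the tested
quantities.

### Deletion vs. two flanking duplications

A local dip is ambiguous from local contrast alone: one deletion, or two
flanking duplications? Only the absolute level against the external
all-targets reference separates them. A loss segment at r ≤ −0.415 in
absolute terms is annotated "deletion (absolute)"; a neutral segment
sandwiched between two gain segments is annotated "two flanking
duplications". With a single target region no external reference exists
and aberrant calls are annotated indeterminate.

## Background CNV scan from ejected reads

Only reads the sampler actually ejected are used — accepted reads that
align off-target would create falsely high local coverage. Depth is
taken genome-wide in 10 kb bins; target regions, common CNV regions and
centromeres/telomeres are masked (any BED is accepted; fixtures use
synthetic masks). Per chromosome, the reference is the mean depth of
that chromosome's unmasked bins (a median option exists but the mean is
the default). Windows of 1 Mb with at least 50% unmasked bins are scored
by the log2 of their unmasked mean depth against the reference, using
the same cut-offs as the target caller; consecutive same-direction
windows merge into one call. At ~4–5x ejected-read depth this resolves
Mb-scale events: a heterozygous 1 Mb deletion reports ≈ −1 and a
single-copy gain ≈ +0.58.

One bias is worth knowing: the chromosome carrying the event contributes
its own windows to the chromosome mean, pulling the reported level
toward 0 by log2(1 + (cn/2 − 1)·S/G) for an event of size S on a
chromosome of size G. On real chromosomes (≥ 90 Mb) this is negligible;
toy fixtures for the background scan therefore use 30/20/15 Mb contigs
so a 1 Mb event stays a realistically small fraction (closed-form
expected levels −0.976 and +0.561 for the deletion and gain fixtures).

## Breakpoint junctions and architectures

Each pair of consecutive alignment segments along a read is one raw
junction observation: the exit side of the first segment joined to the
entry side of the second, with orientations from strands. Sides are
canonically ordered, so a junction crossed in either read orientation
yields the identical observation. Observations cluster by
single-linkage (both sides within 50 bp, orientations matching);
cluster positions are member medians (robust to soft-clip jitter),
support counts distinct reads, and clusters below 3 reads are dropped;
both knobs are configurable and deliberately conservative for ~12 kb
reads at ≥ 17x. Micro-homology is reported as the min–max interval of
member positions rather than resolved to a single base.

Typing follows orientation algebra: different contigs → translocation;
equal orientations → inversion-like; tail@lower + head@higher →
deletion-like; head@lower + tail@higher → tandem-duplication-like; a
same-position tail/head pair is ambiguous (it is the reference
adjacency). Breakpoint verification returns `confirmed_nucleotide` when
a sufficiently supported junction side falls in the expected interval —
for translocations one side suffices, because the partner side may lie
in repeats that were never targeted — `supported_depth_only` when only
an aberrant CN segment overlaps, else `not_confirmed`.

For complex loci, copy-number segments plus junctions form a segment
graph: nodes are reference blocks with carrier-haplotype multiplicities
(total CN minus the intact haplotype's contribution), edges are
reference adjacencies plus observed junctions connecting segment ends,
between a left and right anchor. The robust construction cuts the locus
at junction positions (far more precise than window-snapped CN edges)
and reads each block's copy number off the log2 track. Architecture
enumeration is an exhaustive depth-first search over anchor-to-anchor
walks that use each segment exactly its multiplicity times and traverse
only graph edges (entering a segment at its head runs it forward, at
its tail reverse); solutions are deduplicated and capped (default 100,
with a truncation flag), with a hard total-multiplicity cap of 20 that
keeps exhaustive search exact. Walks are not obliged to use every
junction, and a repeated block that no read spans genuinely admits
multiple walks — the enumeration then returns several solutions, which
is the scientifically correct answer, not a failure mode.

## The synthetic generator

The generator emits exactly what the analysis consumes — a
sequencing-summary table and alignment segments, plus a truth set — and
nothing the analysis does not (no base-level sequence, no re-mapping).
Variants are planted as explicit derived haplotypes: each derived
chromosome is a list of oriented reference blocks, normalized so
sequence-contiguous neighbours merge and every remaining internal
boundary is a genuine junction. Reads are sampled in derived
coordinates and mapped back through the blocks. This single mechanism
yields depth proportional to local copy number (for both read classes),
sharp depth steps at breakpoints, split reads meeting exactly at
junctions with correct strands even for inverted blocks, and a truth
set (per-read fates, per-junction supporting reads) by construction.
Reads are reverse-complemented with probability 1/2, exercising the
canonical-side logic.

Defaults emulate a single-sample MinION run: 28x over targets with
12 kb on-target N50, 5x genome-wide ejected depth with 560 bp N50, mean
read quality 14 (s.d. 3) with an explicit 5% of reads below Q10, and a
toy genome of three contigs (5/5/3 Mb). Read lengths are log-normal
with the location parameter set by the closed form mu = ln(N50) − sigma²
(the length-weighted, i.e. size-biased, log-normal has median
exp(mu + sigma²)), so realized N50s land within a few percent of the
configured values for any sigma. The on-target sigma is 0.45: the
emulated libraries are sheared to ~8–10 kb and short-read-depleted, so
the length distribution is tight around the N50 rather than
long-tailed. This matters beyond realism — a long-tailed length
distribution at 28x produces 40–60 kb coverage excursions of ±0.2–0.3
log2 that are statistically indistinguishable from one-copy steps, and
no caller could then meet the recovery statistics this package tests.
Ejected reads use sigma 0.35 (ejection happens after a roughly constant
decision time) and never split across junctions (at ~560 bp they rarely
span one informatively); they are truncated at the enclosing block
instead.

What the generator does **not** emulate, and what passing tests
therefore do not demonstrate: mappability and GC bias, segmental
duplications (breakpoints are always uniquely placeable, unlike the
real 16p11.2 case), basecalling error, chimeric artefacts, pore-load
drift over a run, and barcode imbalance in multiplexed runs. Depth
noise is compound-Poisson from read sampling only.

Fixture proportions are chosen so the all-targets reference is
dominated by copy-neutral material (large control targets next to a
1 Mb rearranged target), mirroring the clinical design where control
regions are co-targeted precisely to anchor normalization.

## Numerical and interface choices

Internal coordinates are 0-based half-open (BED convention) everywhere;
"chr:start-end" strings in the 1-based inclusive clinical dialect are
converted on parse (start − 1) and on display, with thousands
separators stripped; both conventions round-trip. The end base of an
inclusive string is taken as included; at the printed rounding of the
worked examples (898 kb, 1.47 Mb) this choice is not distinguishable
from the half-open reading, and it is the documented default.
Assembly labels on regions are metadata only — no liftover. SAM/BAM
reference spans are computed from the CIGAR (M/=/X/D/N consume
reference) by an in-package interpreter; split-alignment order along a
read comes from the query offset (leading clips, trailing clips for
reverse alignments). A plain TSV alignment dialect is first-class so the
whole pipeline runs on text fixtures. Depth binning is exact (vectorized
per-bin base counting, verified against per-base pileup); the last bin
of an interval may be short and is weighted by its true width
everywhere. Output ordering is deterministic (genome contig order, then
start), and identical seeds give byte-identical generator output.

Problem sizes throughout the test surface are desk-scale by design:
toy genomes of 13–65 Mb, events of 0.15–1 Mb, 50-replicate recovery
statistics — large enough that the tested quantities (log2 levels,
boundary placement, junction recall) sit in the same statistical regime
as the emulated runs, small enough to run routinely.

## Known limitations

The caller has no GC/mappability correction and no mosaic-fraction
model; background sensitivity below ~100 kb is out of scope (ejected
depth is ~5x); the chromosome-mean bias above is not corrected, only
documented; junction clustering assumes breakpoints are unique in the
reference (no repeat-aware rescue); architecture enumeration assumes a
single locus chain between two anchors and integer multiplicities from
a heterozygous carrier by default.
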