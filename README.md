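# asval — structural-variant validation from nanopore adaptive sampling

Clinical genetics routinely finds large structural variants (SVs) —
deletions, duplications, translocations, complex rearrangements — by
microarray or short-read sequencing, and then has to *confirm* them with
a second, independent method. Probe-based assays (FISH, MLPA, qPCR)
confirm presence but say nothing about breakpoints or architecture, and
each new target needs new reagents. Nanopore **adaptive sampling** is an
attractive alternative: the sequencer compares the first few hundred
bases of every molecule against an in-silico target list and ejects
non-matching molecules from the pore. One run yields ~30x of long reads
over the targeted regions plus a thin (~5x) genome-wide carpet of short
ejected reads — enough to confirm a variant, map its breakpoints to
nucleotide resolution, and reconstruct its architecture, with no custom
wet-lab work per target.

`asval` implements the analysis side of that strategy as a tested,
reusable Python library, for people evaluating or deploying
adaptive-sampling SV confirmation:

* **run_qc** — read-fate classification (`end_reason ==
  "data_service_unblock_mux_change"` marks ejected reads), Q10
  filtering, N50s, per-region depth and target enrichment;
* **cnv_target** — copy number over targets from 500 bp binned depth,
  normalized as r = log2(depth / mu) against the mean depth mu of *all*
  targeted regions in the sample (the external reference that lets a
  dip be read as one deletion rather than two flanking duplications);
  integer copy number via cn = round(baseline·2^r), baseline 2 on
  autosomes and 1 on male chrX, so a heterozygous deletion sits at
  r = −1 and a single-copy gain at r ≈ +0.585;
* **cnv_background** — a genome-wide CNV scan using *only* the ejected
  reads: 10 kb bins, exclusion masking, 1 Mb windows against each
  chromosome's mean — Mb-scale events are visible far outside the
  targets;
* **breakpoints** — split-read junction extraction, single-linkage
  clustering (50 bp tolerance, ≥3 spanning reads), orientation-algebra
  typing (DEL/DUP/INV-like, TRA), breakpoint verification including
  one-sided translocation targeting, and exhaustive enumeration of
  rearrangement architectures from copy numbers plus junctions;
* **synthetic** — a generator of complete synthetic runs (summary +
  alignments + truth set) with planted SVs, built on explicit derived
  haplotypes so depth, split reads and junction strands all follow from
  one mechanism;
* **core_io** — BED / clinical "chr:start-end" coordinate tables (both
  conventions, round-tripping), FASTA target extraction, MinKNOW-style
  summaries, SAM/BAM or a plain TSV alignment dialect, bedGraph and
  VCF-like outputs.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Simulate a run with a planted TRIP-QUINT-TRIP rearrangement (triplicated
flanks around a quintuplicated, inverted core — total copy numbers
4/6/4 inside a 1 Mb target, large control targets alongside), then run
the pipeline:

```python
from asval import run_qc, breakpoints
from asval.synthetic import fixture_configs, simulate_run
from asval.cnv_target import call_target_cnv

cfg = fixture_configs(seed=7)["trip_quint_trip"]
run = simulate_run(cfg)
records = run_qc.quality_filter(run_qc.classify_reads(run.records))
passing = {r.read_id for r in records}
segments = [s for s in run.segments if s.read_id in passing]

stats = run_qc.run_summary(records, segments, cfg.targets, cfg.genome)
calls, track = call_target_cnv(segments, cfg.targets, cfg.genome)
juncs = breakpoints.cluster_junctions(breakpoints.extract_raw_junctions(segments))
```

which prints (formatting elided):

```
reads: 15145 on-target / 123698 off-target
on-target N50: 11962 bp   off-target N50: 560 bp
autosomal target depth: 34.9x   genome: 17.6x   enrichment: 2.0x

chr2:1250000-1400000  gain  log2=+1.05  CN=4
chr2:1400000-1600000  gain  log2=+1.66  CN=6
chr2:1600000-1750000  gain  log2=+0.93  CN=4

INV-like  chr2:1250000(head) -- chr2:1250000(head)  support=11
INV-like  chr2:1400000(head) -- chr2:1400000(head)  support=6
INV-like  chr2:1600000(tail) -- chr2:1600000(tail)  support=9
INV-like  chr2:1750000(tail) -- chr2:1750000(tail)  support=14
```

Reading the output: realized N50s match the configured 12 kb / 560 bp
read-length targets; enrichment is modest here only because this desk
fixture targets 5.5 Mb of a 13 Mb toy genome (a real run targets ~1% of
a genome). The depth track recovers the planted copy-number staircase —
log2 ratios ≈ 1.0 / 1.585 / 1.0, i.e. integer copy numbers 4 / 6 / 4 —
with segment boundaries on the planted breakpoints, and clustering the
split reads recovers the four fold-back (inversion-type) junctions at
exactly the planted positions, each supported by ≥ 6 spanning reads.
Feeding the same track and junctions to
`breakpoints.graph_from_depth_and_junctions` +
`breakpoints.enumerate_architectures` reconstructs the derived
haplotype's segment walk.

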