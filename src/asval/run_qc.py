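"""Read-fate classification, quality filtering and run-level statistics.

Adaptive sampling ejects non-matching molecules; MinKNOW records this in
the summary sheet's ``end_reason`` column. A read is off-target exactly
when ``end_reason == "data_service_unblock_mux_change"``; every other
reason (the read was allowed to finish) counts as on-target. Reads with
mean quality below Q10 are discarded before any depth arithmetic.

Enrichment is defined as mean autosomal on-target depth divided by mean
genome-wide depth (all passing reads over the whole genome), which is the
arithmetic used when quoting enrichment factors for adaptive-sampling
runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .types import (
    AlignmentSegment,
    Fate,
    GenomeLayout,
    ReadRecord,
    Sex,
    TargetRegion,
    UNBLOCK_END_REASON,
)

logger = logging.getLogger(__name__)


def classify_reads(records: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Assign the adaptive-sampling fate to every record, in place.

    Off-target iff the end reason is exactly the ejection marker; an
    empty/missing end reason is flagged on-target with a logged warning.
    """
    records = list(records)
    n_blank = 0
    for r in records:
        if not r.end_reason:
            n_blank += 1
            r.fate = Fate.ON_TARGET
        elif r.end_reason == UNBLOCK_END_REASON:
            r.fate = Fate.OFF_TARGET
        else:
            r.fate = Fate.ON_TARGET
    if n_blank:
        logger.warning("%d records had an empty end_reason; labelled on-target", n_blank)
    return records


def quality_filter(records: Iterable[ReadRecord], min_q: float = 10.0) -> list[ReadRecord]:
    """Keep reads whose mean quality is at least ``min_q`` (boundary kept)."""
    records = list(records)
    kept = [r for r in records if r.mean_q >= min_q]
    n_discarded = len(records) - len(kept)
    if n_discarded:
        logger.info("discarded %d/%d reads below Q%g", n_discarded, len(records), min_q)
    return kept


def read_n50(lengths: Sequence[int]) -> int:
    """N50: largest L such that reads of length >= L hold half the bases."""
    if len(lengths) == 0:
        raise ValueError("N50 is undefined for an empty length set")
    arr = np.sort(np.asarray(lengths))[::-1]
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(arr[idx])


def target_fraction(regions: Sequence[TargetRegion], genome: GenomeLayout) -> float:
    """Fraction of the genome covered by the targets, in percent."""
    return 100.0 * sum(r.length for r in regions) / genome.total_length


def aligned_bases_in_region(
    segments: Iterable[AlignmentSegment], region: TargetRegion
) -> int:
    total = 0
    for s in segments:
        if s.contig != region.contig:
            continue
        total += max(0, min(s.end, region.end) - max(s.start, region.start))
    return total


@dataclass
class RunStats:
    """Run-level sequencing statistics for one adaptive-sampling run."""

    n_reads_on: int
    n_reads_off: int
    gigabases_passing: float
    on_target_n50: int
    off_target_n50: int
    region_depth: dict[str, float] = field(default_factory=dict)
    autosomal_target_depth: float = 0.0
    chrx_target_depth: float | None = None
    genome_depth: float = 0.0
    enrichment: float = 0.0


def run_summary(
    records: Sequence[ReadRecord],
    segments: Sequence[AlignmentSegment],
    regions: Sequence[TargetRegion],
    genome: GenomeLayout,
) -> RunStats:
    """Compute the run statistics table.

    ``records`` must already be classified and quality-filtered; only
    segments belonging to passing reads contribute depth. Per-region
    depth uses all passing reads regardless of fate (stray ejected reads
    inside a target still count). When the sample is male, chrX regions
    are excluded from the autosomal on-target mean and from enrichment.
    """
    passing_ids = {r.read_id for r in records}
    segs = [s for s in segments if s.read_id in passing_ids]

    on_lengths = [r.length for r in records if r.fate == Fate.ON_TARGET]
    off_lengths = [r.length for r in records if r.fate == Fate.OFF_TARGET]

    region_depth: dict[str, float] = {}
    # bucket segments by contig once; regions are few
    by_contig: dict[str, list[AlignmentSegment]] = {}
    for s in segs:
        by_contig.setdefault(s.contig, []).append(s)
    for region in regions:
        bases = aligned_bases_in_region(by_contig.get(region.contig, []), region)
        region_depth[region.name] = bases / region.length

    male = genome.sex == Sex.MALE
    auto_regions = [r for r in regions if not (male and genome.is_x(r.contig))]
    x_regions = [r for r in regions if genome.is_x(r.contig)]
    if not auto_regions:
        raise ValueError("no autosomal target regions; enrichment undefined")
    auto_bases = sum(
        aligned_bases_in_region(by_contig.get(r.contig, []), r) for r in auto_regions
    )
    auto_len = sum(r.length for r in auto_regions)
    autosomal_depth = auto_bases / auto_len

    chrx_depth = None
    if x_regions:
        x_bases = sum(
            aligned_bases_in_region(by_contig.get(r.contig, []), r) for r in x_regions
        )
        chrx_depth = x_bases / sum(r.length for r in x_regions)

    total_aligned = sum(s.span for s in segs)
    genome_depth = total_aligned / genome.total_length
    if genome_depth == 0:
        raise ValueError("no aligned bases; genome depth is zero")

    return RunStats(
        n_reads_on=len(on_lengths),
        n_reads_off=len(off_lengths),
        gigabases_passing=sum(r.length for r in records) / 1e9,
        on_target_n50=read_n50(on_lengths) if on_lengths else 0,
        off_target_n50=read_n50(off_lengths) if off_lengths else 0,
        region_depth=region_depth,
        autosomal_target_depth=autosomal_depth,
        chrx_target_depth=chrx_depth,
        genome_depth=genome_depth,
        enrichment=autosomal_depth / genome_depth,
    )
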