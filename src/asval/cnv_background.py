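"""Genome-wide CNV scan from the ejected (off-target) reads.

Adaptive sampling ejects most molecules after ~500 bp, which thinly but
evenly tiles the whole genome. Those rejected reads suffice to detect
large (Mb-scale) copy-number changes anywhere, including far outside the
targeted regions. Only reads the sampler actually ejected are used:
stray accepted reads aligning off target would create falsely high
coverage. Target regions, common CNV regions and centromeres/telomeres
are masked out, depth is taken in 10 kb bins, and 1 Mb windows are
compared with the mean depth of their own chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from . import core_io
from .cnv_target import DEFAULT_GAIN_CUT, DEFAULT_LOSS_CUT, binned_depth
from .types import (
    AlignmentSegment,
    DepthProfile,
    GenomeLayout,
    ReadClass,
    SegmentStatus,
    TargetRegion,
)

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 10_000
DEFAULT_WINDOW = 1_000_000


class ExclusionSet:
    """Merged interval mask (targets, common CNVs, centromeres/telomeres)."""

    def __init__(self, intervals: Sequence[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            if end <= start:
                raise ValueError(f"invalid exclusion interval {contig}:{start}-{end}")
            self._trees.setdefault(contig, IntervalTree()).addi(start, end)
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "ExclusionSet":
        regions = core_io.read_regions(path, convention="bed_0_half_open")
        return cls([(r.contig, r.start, r.end) for r in regions])

    @classmethod
    def from_regions(cls, regions: Sequence[TargetRegion]) -> "ExclusionSet":
        return cls([(r.contig, r.start, r.end) for r in regions])

    def union(self, other: "ExclusionSet") -> "ExclusionSet":
        return ExclusionSet(list(self) + list(other))

    def __iter__(self):
        for contig, tree in self._trees.items():
            for iv in sorted(tree):
                yield (contig, iv.begin, iv.end)

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree.overlap(start, end)) if tree is not None else False


def background_profile(
    alignments: Sequence[AlignmentSegment],
    genome: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> DepthProfile:
    """Genome-wide binned depth from off-target reads only.

    Segments must carry read-class labels; anything not labelled
    off-target is ignored, and an input with no off-target segments at
    all is an error. Bins inside target regions are still computed here;
    masking is the scan's concern.
    """
    off = [s for s in alignments if s.read_class == ReadClass.OFF_TARGET]
    if not off:
        raise ValueError("no off-target alignment segments; cannot build background profile")
    intervals = [(name, 0, length) for name, length in genome.contigs]
    return binned_depth(off, intervals, bin_size, read_class="off_target_only")


@dataclass
class BackgroundCall:
    """One merged aberrant window run from the background scan."""

    contig: str
    start: int
    end: int
    mean_log2: float
    direction: SegmentStatus
    n_windows: int


def background_scan(
    profile: DepthProfile,
    exclusions: Optional[ExclusionSet] = None,
    window: int = DEFAULT_WINDOW,
    loss_cut: float = DEFAULT_LOSS_CUT,
    gain_cut: float = DEFAULT_GAIN_CUT,
    min_unmasked_frac: float = 0.5,
    robust: bool = False,
) -> list[BackgroundCall]:
    """Scan the genome-wide off-target depth profile for large CNVs.

    Per chromosome, the reference level is the mean depth of that
    chromosome's unmasked bins (median when ``robust``). Windows of
    ``window`` bp with at least ``min_unmasked_frac`` unmasked bins are
    scored by the log2 of their unmasked mean depth against the
    reference; windows at or beyond a cut-off are aberrant, and
    consecutive same-direction windows merge into one call.
    """
    if window < profile.bin_size:
        raise ValueError("window must be at least one bin")
    exclusions = exclusions or ExclusionSet()

    by_contig: dict[str, list[int]] = {}
    for i, (contig, _, _) in enumerate(profile.bins):
        by_contig.setdefault(contig, []).append(i)

    calls: list[BackgroundCall] = []
    for contig, idxs in by_contig.items():
        idxs = np.asarray(idxs)
        depth = np.asarray([profile.depth[i] for i in idxs], dtype=float)
        starts = np.asarray([profile.bins[i][1] for i in idxs])
        ends = np.asarray([profile.bins[i][2] for i in idxs])
        masked = np.asarray(
            [exclusions.overlaps(contig, s, e) for s, e in zip(starts, ends)]
        )
        if masked.all():
            logger.warning("chromosome %s fully masked; skipped", contig)
            continue
        unmasked_depth = depth[~masked]
        ref = float(np.median(unmasked_depth)) if robust else float(np.mean(unmasked_depth))
        if ref == 0:
            logger.warning("chromosome %s has zero unmasked depth; skipped", contig)
            continue

        window_rows = []  # (w_start, w_end, r) for scoreable windows, in order
        chrom_end = int(ends.max())
        for w_start in range(0, chrom_end, window):
            w_end = min(w_start + window, chrom_end)
            in_win = (starts >= w_start) & (starts < w_end)
            n_bins = int(in_win.sum())
            if n_bins == 0:
                window_rows.append((w_start, w_end, None))
                continue
            ok = in_win & ~masked
            if int(ok.sum()) < min_unmasked_frac * n_bins:
                window_rows.append((w_start, w_end, None))
                continue
            mean_d = float(np.mean(depth[ok]))
            r = float(np.log2(mean_d / ref)) if mean_d > 0 else float("-inf")
            window_rows.append((w_start, w_end, r))

        current: Optional[dict] = None
        for w_start, w_end, r in window_rows:
            direction = None
            if r is not None:
                if r <= loss_cut:
                    direction = SegmentStatus.LOSS
                elif r >= gain_cut:
                    direction = SegmentStatus.GAIN
            if direction is not None and current is not None and (
                current["direction"] == direction and current["end"] == w_start
            ):
                current["end"] = w_end
                current["r"].append(r)
            elif direction is not None:
                if current is not None:
                    calls.append(_finish_call(contig, current))
                current = {"start": w_start, "end": w_end, "direction": direction, "r": [r]}
            else:
                if current is not None:
                    calls.append(_finish_call(contig, current))
                    current = None
        if current is not None:
            calls.append(_finish_call(contig, current))
    return calls


def _finish_call(contig: str, run: dict) -> BackgroundCall:
    return BackgroundCall(
        contig=contig,
        start=run["start"],
        end=run["end"],
        mean_log2=float(np.mean(run["r"])),
        direction=run["direction"],
        n_windows=len(run["r"]),
    )
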