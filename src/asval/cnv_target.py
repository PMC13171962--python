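"""Copy-number inference over targeted regions from binned read depth.

Depth is computed in 500 bp bins (mosdepth-style mean depth: aligned
bases overlapping the bin divided by bin width). Each bin is normalized
as a log2 ratio against the length-weighted mean depth over *all* target
regions in the sample — the key trick for targeted runs, where no
genome-wide baseline exists and a region's own flanks may themselves be
rearranged. On male samples chrX bins are excluded from the reference
mean and ratioed against half of it (one X copy expected).

Windows of consecutive bins are classified loss/neutral/gain by log2
cut-offs and merged into copy-number segments; integer copy number
follows cn = round(baseline * 2^r).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .types import (
    AlignmentSegment,
    CNSegment,
    DepthProfile,
    GenomeLayout,
    SegmentStatus,
    Sex,
    TargetRegion,
)

#: log2 value assigned to zero-depth bins instead of -inf.
ZERO_DEPTH_FLOOR = -5.0

DEFAULT_LOSS_CUT = -0.415
DEFAULT_GAIN_CUT = 0.32


def _interval_tuple(iv) -> tuple[str, int, int]:
    if isinstance(iv, TargetRegion):
        return (iv.contig, iv.start, iv.end)
    contig, start, end = iv
    return (str(contig), int(start), int(end))


def _binned_bases(
    starts: np.ndarray, ends: np.ndarray, ival_start: int, ival_end: int, bin_size: int
) -> np.ndarray:
    """Aligned bases per bin for one interval, fully vectorized.

    ``starts``/``ends`` must already be clipped to [ival_start, ival_end)
    and non-empty after clipping.
    """
    n_bins = -(-(ival_end - ival_start) // bin_size)
    bases = np.zeros(n_bins)
    if starts.size == 0:
        return bases
    s = starts - ival_start
    e = ends - ival_start
    b_s = s // bin_size
    b_e = (e - 1) // bin_size
    same = b_s == b_e
    np.add.at(bases, b_s[same], (e - s)[same])
    multi = ~same
    if multi.any():
        sm, em, bs, be = s[multi], e[multi], b_s[multi], b_e[multi]
        np.add.at(bases, bs, (bs + 1) * bin_size - sm)
        np.add.at(bases, be, em - be * bin_size)
        # bins fully covered between first and last: difference trick
        diff = np.zeros(n_bins + 1)
        inner = be > bs + 1
        if inner.any():
            np.add.at(diff, bs[inner] + 1, bin_size)
            np.add.at(diff, be[inner], -bin_size)
            bases += np.cumsum(diff[:-1])
    return bases


def binned_depth(
    alignments: Sequence[AlignmentSegment],
    intervals: Sequence,
    bin_size: int,
    read_class: str = "all_passing",
) -> DepthProfile:
    """Mean depth in fixed-size bins tiling each interval.

    Per-bin depth = aligned bases overlapping the bin / bin width, with
    alignments clipped at bin boundaries (mosdepth-equivalent). The last
    bin of an interval may be short.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ivals = [_interval_tuple(iv) for iv in intervals]
    for contig, start, end in ivals:
        if end - start < 1:
            raise ValueError(f"interval {contig}:{start}-{end} shorter than 1 bp")

    by_contig: dict[str, list[tuple[int, int]]] = {}
    for seg in alignments:
        by_contig.setdefault(seg.contig, []).append((seg.start, seg.end))
    arrays = {
        c: (np.asarray([p[0] for p in v]), np.asarray([p[1] for p in v]))
        for c, v in by_contig.items()
    }

    bins: list[tuple[str, int, int]] = []
    depth: list[float] = []
    for contig, start, end in ivals:
        n_bins = -(-(end - start) // bin_size)
        edges_lo = start + bin_size * np.arange(n_bins)
        edges_hi = np.minimum(edges_lo + bin_size, end)
        if contig in arrays:
            s, e = arrays[contig]
            keep = (e > start) & (s < end)
            cs = np.clip(s[keep], start, end)
            ce = np.clip(e[keep], start, end)
            bases = _binned_bases(cs, ce, start, end, bin_size)
        else:
            bases = np.zeros(n_bins)
        widths = edges_hi - edges_lo
        bins.extend((contig, int(lo), int(hi)) for lo, hi in zip(edges_lo, edges_hi))
        depth.extend(bases / widths)
    return DepthProfile(bins=bins, depth=depth, bin_size=bin_size, read_class=read_class)


@dataclass
class Log2Track:
    """Per-bin log2 depth ratios against the all-targets reference mean."""

    bins: list[tuple[str, int, int]]
    depth: np.ndarray
    log2: np.ndarray
    mu: float
    baseline: np.ndarray  # per-bin expected copy number (2, or 1 on male X)
    zero_floor: float = ZERO_DEPTH_FLOOR


def target_log2(
    profile: DepthProfile,
    genome: GenomeLayout,
    zero_floor: float = ZERO_DEPTH_FLOOR,
) -> Log2Track:
    """Normalize a target depth profile to log2 ratios.

    The reference level mu is the length-weighted mean depth over all
    target bins; on male samples chrX bins are excluded from mu and
    ratioed against mu/2 instead (hemizygous baseline), so a normal male
    X sits at r = 0 with copy-number baseline 1.

    No separate treatment of the ejected-read contribution is needed:
    stray ejected reads inside a copy-number variant scale with the
    local copy number just like accepted reads (both are sampled from
    the same genome), so the plain depth ratio is already an unbiased
    copy-number ratio.
    """
    depth = np.asarray(profile.depth, dtype=float)
    widths = np.asarray([e - s for _, s, e in profile.bins], dtype=float)
    male = genome.sex == Sex.MALE
    is_x = np.asarray([male and genome.is_x(c) for c, _, _ in profile.bins])
    norm_mask = ~is_x
    if not norm_mask.any():
        raise ValueError("no autosomal bins available for normalization")
    mu = float(np.average(depth[norm_mask], weights=widths[norm_mask]))
    if mu <= 0:
        raise ValueError("degenerate run: reference mean depth is zero")
    ref = np.where(is_x, mu / 2.0, mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(depth / ref)
    r[depth <= 0] = zero_floor
    baseline = np.where(is_x, 1, 2)
    return Log2Track(
        bins=list(profile.bins),
        depth=depth,
        log2=r,
        mu=mu,
        baseline=baseline,
        zero_floor=zero_floor,
    )


def _bin_groups(bins: list[tuple[str, int, int]]) -> list[tuple[int, int]]:
    """Maximal runs of adjacent bins (same contig, touching coordinates)."""
    groups = []
    start = 0
    for i in range(1, len(bins)):
        prev, cur = bins[i - 1], bins[i]
        if cur[0] != prev[0] or cur[1] != prev[2]:
            groups.append((start, i))
            start = i
    if bins:
        groups.append((start, len(bins)))
    return groups


def _window_r(track: Log2Track, lo: int, hi: int, mu: Optional[float] = None) -> float:
    """Length-weighted mean log2 over bins [lo, hi), via mean depth."""
    if mu is None:
        mu = track.mu
    widths = np.asarray([e - s for _, s, e in track.bins[lo:hi]], dtype=float)
    mean_depth = float(np.average(track.depth[lo:hi], weights=widths))
    ref = mu / 2.0 if track.baseline[lo] == 1 else mu
    if mean_depth == 0:
        return track.zero_floor
    return float(np.log2(mean_depth / ref))


def _status_of(r: float, loss_cut: float, gain_cut: float) -> SegmentStatus:
    if r <= loss_cut:
        return SegmentStatus.LOSS
    if r >= gain_cut:
        return SegmentStatus.GAIN
    return SegmentStatus.NEUTRAL


def _cn_of(r: float, baseline: int, status: SegmentStatus) -> int:
    cn = max(0, round(baseline * 2.0**r))
    # keep the integer estimate consistent with the thresholded status
    if status == SegmentStatus.GAIN:
        cn = max(cn, baseline + 1)
    elif status == SegmentStatus.LOSS:
        cn = min(cn, baseline - 1)
    return cn


def segment_and_call(
    track: Log2Track,
    window_bins: int = 10,
    loss_cut: float = DEFAULT_LOSS_CUT,
    gain_cut: float = DEFAULT_GAIN_CUT,
    min_windows: int = 3,
    recenter: bool = True,
) -> list[CNSegment]:
    """Segment the log2 track into copy-number segments.

    Non-overlapping windows of ``window_bins`` bins are classified by the
    log2 cut-offs (values exactly at a cut count as aberrant) and
    adjacent same-status windows merge into runs; runs shorter than
    ``min_windows`` windows are absorbed into the neighbouring run with
    the closest level. Each aberrant run is then refined by recursive
    binary changepoint splitting: the run splits at the window boundary
    maximizing the level contrast, but only where the two sides round to
    *different* integer copy numbers — so noise blips cannot fragment a
    plateau, while genuinely distinct plateaus (e.g. triplicated flanks
    around a quintuplicated core) separate cleanly.

    ``recenter`` re-estimates the diploid reference from the windows
    classified neutral and renormalizes before segmenting. The
    all-targets mean is biased upward when a rearranged locus is a
    non-trivial fraction of the targeted material (its extra copies
    inflate the mean); recentering pins copy-neutral windows at r = 0
    regardless of target composition.
    """
    if len(track.bins) == 0:
        raise ValueError("empty log2 track")

    groups = _bin_groups(track.bins)
    window_bounds = [
        (w_lo, min(w_lo + window_bins, g_hi))
        for g_lo, g_hi in groups
        for w_lo in range(g_lo, g_hi, window_bins)
    ]
    mu = track.mu
    if recenter:
        for _ in range(3):
            rs = np.asarray([_window_r(track, lo, hi, mu) for lo, hi in window_bounds])
            weights = np.asarray(
                [track.bins[hi - 1][2] - track.bins[lo][1] for lo, hi in window_bounds],
                dtype=float,
            )
            neutral = (rs > loss_cut) & (rs < gain_cut)
            if not neutral.any():
                break
            shift = float(np.average(rs[neutral], weights=weights[neutral]))
            if abs(shift) < 1e-3:
                break
            mu *= 2.0**shift

    segments: list[CNSegment] = []
    for g_lo, g_hi in groups:
        pieces = _dp_partition(track, g_lo, g_hi, window_bins, min_windows, mu)
        merged: list[list[int]] = []
        for lo, hi in pieces:
            r = _window_r(track, lo, hi, mu)
            status = _status_of(r, loss_cut, gain_cut)
            baseline = int(track.baseline[lo])
            cn = _cn_of(r, baseline, status)
            if merged and merged[-1][2] == status and merged[-1][3] == cn:
                merged[-1][1] = hi
            else:
                merged.append([lo, hi, status, cn])
        _polish_boundaries(track, merged, window_bins, min_windows, mu)
        for lo, hi, status, _cn in merged:
            r = _window_r(track, lo, hi, mu)
            status = _status_of(r, loss_cut, gain_cut)
            baseline = int(track.baseline[lo])
            segments.append(
                CNSegment(
                    contig=track.bins[lo][0],
                    start=track.bins[lo][1],
                    end=track.bins[hi - 1][2],
                    mean_log2=r,
                    cn_estimate=_cn_of(r, baseline, status),
                    n_bins=hi - lo,
                    status=status,
                )
            )
    return segments


#: multiplier on the estimated window variance for the segmentation
#: penalty. BIC-flavoured but inflated well beyond 2 ln n because the
#: noise between neighbouring windows is correlated over roughly a read
#: length and compound-Poisson coverage produces occasional sustained
#: excursions; calibrated so those excursions stay below the penalty
#: while one-copy steps over window-scale plateaus clear it easily.
SPLIT_PENALTY_FACTOR = 28.0


def _dp_partition(
    track: Log2Track,
    g_lo: int,
    g_hi: int,
    window_bins: int,
    min_windows: int,
    mu: float,
) -> list[tuple[int, int]]:
    """Optimal piecewise-constant partition of one region's window track.

    Window-mean log2 values are fit minimizing within-segment squared
    error plus an L0 penalty per boundary (beta = SPLIT_PENALTY_FACTOR *
    sigma^2 * ln n, sigma estimated robustly from adjacent-window
    differences so genuine steps do not inflate it), with segments at
    least ``min_windows`` windows long. Genuine copy-number steps (1.0
    in log2 for neutral vs two extra copies, 0.585 for triplicated vs
    quintuplicated) reduce the error far beyond the penalty; noise
    excursions do not. Returns bin-index ranges.
    """
    cuts = [g_lo + k * window_bins for k in range(0, -(-(g_hi - g_lo) // window_bins))]
    cuts.append(g_hi)
    n = len(cuts) - 1
    if n < 2 * min_windows:
        return [(g_lo, g_hi)]
    r = np.asarray([_window_r(track, cuts[k], cuts[k + 1], mu) for k in range(n)])
    diffs = np.diff(r)
    sigma = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2)
    sigma = max(sigma, 1e-6)
    beta = SPLIT_PENALTY_FACTOR * sigma * sigma * np.log(n)

    csum = np.concatenate([[0.0], np.cumsum(r)])
    csum2 = np.concatenate([[0.0], np.cumsum(r * r)])

    def sse(i: int, j: int) -> float:  # windows [i, j)
        s = csum[j] - csum[i]
        return float(csum2[j] - csum2[i] - s * s / (j - i))

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -beta  # the first segment carries no boundary penalty
    for j in range(min_windows, n + 1):
        for i in range(0, j - min_windows + 1):
            if not np.isfinite(best[i]):
                continue
            cost = best[i] + beta + sse(i, j)
            if cost < best[j]:
                best[j] = cost
                prev[j] = i
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(prev[bounds[-1]]))
    bounds = bounds[::-1]
    return [(cuts[i], cuts[j]) for i, j in zip(bounds, bounds[1:])]


def _polish_boundaries(
    track: Log2Track,
    merged: list[list],
    window_bins: int,
    min_windows: int,
    mu: float,
    reach: int = 5,
) -> None:
    """Re-place each segment boundary against the quantized copy-number model.

    The unconstrained least-squares fit can attach a short noise
    excursion next to a boundary to the wrong side. With the two
    segments' integer copy numbers fixed, the expected levels are known
    (log2(cn/baseline)), so the boundary is moved (within ``reach``
    windows) to minimize the summed squared distance of each window to
    its side's expected level. Modifies ``merged`` ([lo, hi, status, cn]
    rows) in place.
    """
    for a, b in zip(merged, merged[1:]):
        cn_a, cn_b = a[3], b[3]
        if cn_a == cn_b:
            continue
        baseline = int(track.baseline[a[0]])
        level_a = track.zero_floor if cn_a == 0 else float(np.log2(cn_a / baseline))
        level_b = track.zero_floor if cn_b == 0 else float(np.log2(cn_b / baseline))
        cut = b[0]
        lo_limit = a[0] + min_windows * window_bins
        hi_limit = b[1] - min_windows * window_bins
        candidates = [
            c
            for c in range(cut - reach * window_bins, cut + reach * window_bins + 1, window_bins)
            if lo_limit <= c <= hi_limit
        ]
        if len(candidates) <= 1:
            continue
        w_r = {
            w: _window_r(track, w, min(w + window_bins, b[1]), mu)
            for w in range(min(candidates), max(candidates), window_bins)
        }
        best_c, best_cost = cut, float("inf")
        for c in candidates:
            cost = 0.0
            for w, r in w_r.items():
                level = level_a if w < c else level_b
                cost += (r - level) ** 2
            if cost < best_cost:
                best_cost, best_c = cost, c
        if best_c != cut:
            a[1] = best_c
            b[0] = best_c


def call_target_cnv(
    alignments: Sequence[AlignmentSegment],
    targets: Sequence[TargetRegion],
    genome: GenomeLayout,
    bin_size: int = 500,
    **segment_kwargs,
) -> tuple[list[CNSegment], Log2Track]:
    """Full target-CNV stage: binned depth -> log2 track -> segments.

    ``alignments`` are the passing-read segments, all fates included
    (every passing read aligning within the targets contributes).
    """
    profile = binned_depth(alignments, targets, bin_size)
    track = target_log2(profile, genome)
    return segment_and_call(track, **segment_kwargs), track


DELETION_ABSOLUTE = "deletion (absolute)"
DUPLICATION_ABSOLUTE = "duplication (absolute)"
TWO_FLANKING_DUPS = "two flanking duplications"
INDETERMINATE = "indeterminate - no external reference"


def disambiguate_del_vs_dup(
    segments: Sequence[CNSegment],
    track: Log2Track,
    loss_cut: float = DEFAULT_LOSS_CUT,
    gain_cut: float = DEFAULT_GAIN_CUT,
) -> list[CNSegment]:
    """Annotate calls by whether their *absolute* level supports them.

    A local dip can mean either a deletion or two flanking duplications;
    only the level against the external all-targets reference separates
    the two. A segment at r <= loss_cut in absolute terms is a
    "deletion (absolute)"; a neutral segment sandwiched between two gain
    segments is the signature of "two flanking duplications" (its local
    contrast alone would have looked like a loss). With a single target
    region no external reference exists and calls are indeterminate.
    """
    n_groups = len(_bin_groups(track.bins))
    out = []
    for i, seg in enumerate(segments):
        ann = ""
        if n_groups < 2:
            if seg.status != SegmentStatus.NEUTRAL:
                ann = INDETERMINATE
        elif seg.status == SegmentStatus.LOSS:
            ann = DELETION_ABSOLUTE
        elif seg.status == SegmentStatus.GAIN:
            ann = DUPLICATION_ABSOLUTE
        else:
            left = segments[i - 1] if i > 0 else None
            right = segments[i + 1] if i + 1 < len(segments) else None
            if (
                left is not None
                and right is not None
                and left.contig == seg.contig == right.contig
                and left.status == SegmentStatus.GAIN
                and right.status == SegmentStatus.GAIN
            ):
                ann = TWO_FLANKING_DUPS
        out.append(replace(seg, annotation=ann))
    return out
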