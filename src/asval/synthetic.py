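"""Synthetic adaptive-sampling runs with planted structural variants.

The generator emits what the downstream analysis actually consumes: a
MinKNOW-style sequencing summary and a set of alignment segments, plus a
truth set. No sequence-level simulation or re-mapping is performed.

Structural variants are planted by building explicit *derived haplotypes*:
each haplotype is a list of derived chromosomes, and each derived
chromosome is a concatenation of oriented reference blocks ("pieces").
Reads are sampled along derived coordinates and mapped back through the
pieces, so

* local read depth is automatically proportional to copy number,
* reads crossing a block boundary split into supplementary-style
  alignment segments meeting exactly at the junction with correct
  strands, and
* the truth junctions are exactly the non-contiguous piece boundaries.

Two read classes mirror adaptive sampling: accepted ("on-target") reads
start inside targeted material and are long (log-normal, N50 ~ 12 kb);
ejected ("off-target") reads land uniformly genome-wide and are short
(N50 ~ 560 bp) because sequencing stops once the pore decision is made.
"""

from __future__ import annotations

import json
import math
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import core_io
from .types import (
    AlignmentSegment,
    Role,
    Fate,
    GenomeLayout,
    Junction,
    JunctionSide,
    Orientation,
    ReadClass,
    ReadRecord,
    Sex,
    TargetRegion,
    UNBLOCK_END_REASON,
)

#: end_reason written for accepted reads.
ACCEPT_END_REASON = "signal_positive"


# ---------------------------------------------------------------------------
# derived-haplotype machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Piece:
    """One oriented reference block of a derived chromosome."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"piece {self}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"piece {self}: bad strand")

    @property
    def length(self) -> int:
        return self.end - self.start


def _contiguous(a: Piece, b: Piece) -> bool:
    """True when b continues a without a junction (sequence-continuous)."""
    if a.contig != b.contig or a.strand != b.strand:
        return False
    if a.strand == "+":
        return a.end == b.start
    return a.start == b.end


def exit_side(p: Piece) -> JunctionSide:
    """Reference side a read runs out of when leaving piece ``p`` forward."""
    if p.strand == "+":
        return JunctionSide(p.contig, p.end, Orientation.TAIL)
    return JunctionSide(p.contig, p.start, Orientation.HEAD)


def entry_side(p: Piece) -> JunctionSide:
    """Reference side a read runs into when entering piece ``p`` forward."""
    if p.strand == "+":
        return JunctionSide(p.contig, p.start, Orientation.HEAD)
    return JunctionSide(p.contig, p.end, Orientation.TAIL)


def canonical_sides(a: JunctionSide, b: JunctionSide) -> tuple[JunctionSide, JunctionSide]:
    """Order two junction sides canonically (contig, position, orientation)."""
    return (a, b) if a.key() <= b.key() else (b, a)


class DerivedChromosome:
    """A derived chromosome as a normalized list of oriented pieces.

    Sequence-contiguous neighbouring pieces are merged at construction so
    every remaining internal boundary is a genuine breakpoint junction.
    """

    def __init__(self, name: str, pieces: Sequence[Piece]):
        merged: list[Piece] = []
        for p in pieces:
            if merged and _contiguous(merged[-1], p):
                prev = merged.pop()
                if prev.strand == "+":
                    merged.append(Piece(prev.contig, prev.start, p.end, "+"))
                else:
                    merged.append(Piece(prev.contig, p.start, prev.end, "-"))
            else:
                merged.append(p)
        self.name = name
        self.pieces = merged
        self.offsets = np.cumsum([0] + [p.length for p in merged])
        self.length = int(self.offsets[-1])

    def junctions(self) -> list[tuple[JunctionSide, JunctionSide]]:
        """Canonical side pairs of every internal breakpoint."""
        out = []
        for a, b in zip(self.pieces, self.pieces[1:]):
            out.append(canonical_sides(exit_side(a), entry_side(b)))
        return out

    def map_interval(self, x: int, y: int) -> list[tuple[str, int, int, str]]:
        """Map derived interval [x, y) to reference segments, in read order."""
        if not (0 <= x < y <= self.length):
            raise ValueError(f"interval [{x},{y}) outside derived chromosome {self.name}")
        segments = []
        i = bisect_right(self.offsets, x) - 1
        while x < y:
            p = self.pieces[i]
            doff = int(self.offsets[i])
            lo = x - doff
            hi = min(y - doff, p.length)
            if p.strand == "+":
                segments.append((p.contig, p.start + lo, p.start + hi, "+"))
            else:
                segments.append((p.contig, p.end - hi, p.end - lo, "-"))
            x = doff + hi
            i += 1
        return segments

    def derived_intervals_of(self, contig: str, start: int, end: int) -> list[tuple[int, int]]:
        """Derived-coordinate intervals deriving from reference [start, end)."""
        out = []
        for p, doff in zip(self.pieces, self.offsets):
            if p.contig != contig:
                continue
            lo = max(p.start, start)
            hi = min(p.end, end)
            if lo >= hi:
                continue
            if p.strand == "+":
                out.append((int(doff) + lo - p.start, int(doff) + hi - p.start))
            else:
                out.append((int(doff) + p.end - hi, int(doff) + p.end - lo))
        return sorted(out)


def reference_haplotype(genome: GenomeLayout) -> list[DerivedChromosome]:
    return [
        DerivedChromosome(name, [Piece(name, 0, length, "+")])
        for name, length in genome.contigs
    ]


# ---------------------------------------------------------------------------
# planted variants
# ---------------------------------------------------------------------------

SV_KINDS = (
    "deletion",
    "duplication",
    "triplication",
    "quintuplication",
    "translocation",
    "composite",
)


@dataclass
class PlantedSV:
    """A planted structural variant.

    ``loci`` is one (contig, start, end) interval for copy-number events,
    or two (contig, position) breakpoints for a translocation.
    ``expected_cn`` is the total copy number across both haplotypes over
    the affected interval. For ``composite`` events, ``custom_pieces``
    maps contig name -> full derived piece list for the carrier haplotype.
    """

    kind: str
    loci: Sequence[tuple]
    genotype: str = "het"
    expected_cn: Optional[int] = None
    custom_pieces: Optional[dict[str, list[Piece]]] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"genotype must be het or hom, got {self.genotype!r}")
        if self.expected_cn is None:
            self.expected_cn = self._default_cn()

    def _default_cn(self) -> int:
        carrier = {"deletion": 0, "duplication": 2, "triplication": 3,
                   "quintuplication": 5, "translocation": 1, "composite": 1}[self.kind]
        if self.genotype == "het":
            return carrier + 1
        return 2 * carrier

    @property
    def expected_log2(self) -> float:
        if self.expected_cn == 0:
            return float("-inf")
        return math.log2(self.expected_cn / 2.0)


def expected_depth_ratio(sv: PlantedSV, genome: Optional[GenomeLayout] = None) -> tuple[float, float]:
    """Expected depth ratio and log2 for a planted variant.

    The baseline is 2 copies on autosomes (and female X), 1 on male chrX.
    A fully deleted interval (CN 0) yields a ratio of 0 and log2 of -inf.
    """
    if sv.expected_cn < 0:
        raise ValueError("expected_cn must be >= 0")
    contig = sv.loci[0][0]
    baseline = genome.baseline_cn(contig) if genome is not None else 2
    ratio = sv.expected_cn / baseline
    log2 = float("-inf") if ratio == 0 else math.log2(ratio)
    return ratio, log2


def _carrier_pieces(sv: PlantedSV, genome: GenomeLayout) -> dict[str, list[Piece]]:
    """Piece lists for the carrier haplotype's affected contigs."""
    if sv.kind == "composite":
        if not sv.custom_pieces:
            raise ValueError("composite SV requires custom_pieces")
        return sv.custom_pieces
    if sv.kind == "translocation":
        (c1, p1), (c2, p2) = sv.loci
        for c, p in ((c1, p1), (c2, p2)):
            if not 0 < p < genome.length_of(c):
                raise ValueError(f"translocation breakpoint {c}:{p} outside contig")
        len1, len2 = genome.length_of(c1), genome.length_of(c2)
        return {
            c1: [Piece(c1, 0, p1, "+"), Piece(c2, p2, len2, "+")],
            c2: [Piece(c2, 0, p2, "+"), Piece(c1, p1, len1, "+")],
        }
    contig, a, b = sv.loci[0]
    clen = genome.length_of(contig)
    if not (0 <= a < b <= clen):
        raise ValueError(f"SV interval {contig}:{a}-{b} outside contig (length {clen})")
    left = [Piece(contig, 0, a, "+")] if a > 0 else []
    right = [Piece(contig, b, clen, "+")] if b < clen else []
    core = {"deletion": [], "duplication": [Piece(contig, a, b, "+")] * 2,
            "triplication": [Piece(contig, a, b, "+")] * 3,
            "quintuplication": [Piece(contig, a, b, "+")] * 5}[sv.kind]
    return {contig: left + core + right}


def apply_svs(genome: GenomeLayout, svs: Sequence[PlantedSV]) -> tuple[list, list]:
    """Build the two haplotypes (lists of DerivedChromosome) for a sample.

    Haplotype 0 carries every het variant; hom variants go on both.
    At most one variant may touch a given contig.
    """
    hap0 = {name: [Piece(name, 0, length, "+")] for name, length in genome.contigs}
    hap1 = {name: [Piece(name, 0, length, "+")] for name, length in genome.contigs}
    touched: set[str] = set()
    for sv in svs:
        pieces = _carrier_pieces(sv, genome)
        clash = touched & set(pieces)
        if clash:
            raise ValueError(f"multiple SVs touch contig(s) {sorted(clash)}")
        touched |= set(pieces)
        for contig, plist in pieces.items():
            hap0[contig] = plist
            if sv.genotype == "hom":
                hap1[contig] = plist
    names = genome.contig_names()
    return (
        [DerivedChromosome(n, hap0[n]) for n in names],
        [DerivedChromosome(n, hap1[n]) for n in names],
    )


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one simulated adaptive-sampling run.

    Defaults are calibrated to a MinION run: ~28x over targets with 12 kb
    on-target N50, ~5x genome-wide from ejected reads with 560 bp N50,
    mean read quality 14 with ~5% of reads failing the Q10 filter.
    """

    genome: GenomeLayout = field(
        default_factory=lambda: GenomeLayout(
            [("chr1", 5_000_000), ("chr2", 5_000_000), ("chr3", 3_000_000)]
        )
    )
    targets: list[TargetRegion] = field(default_factory=list)
    svs: list[PlantedSV] = field(default_factory=list)
    on_target_depth: float = 28.0
    off_target_depth: float = 5.0
    on_n50: int = 12_000
    off_n50: int = 560
    # length spread reflects a sheared, short-read-depleted library
    # (g-TUBE ~8-10 kb target size): tight around the N50, no long tail
    sigma_on: float = 0.45
    sigma_off: float = 0.35
    q_mean: float = 14.0
    q_sd: float = 3.0
    q_fail_frac: float = 0.05
    junction_read_frac: float = 1.0
    junction_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.on_target_depth <= 0 or self.off_target_depth <= 0:
            raise ValueError("depths must be > 0")
        if self.on_n50 <= 0 or self.off_n50 <= 0:
            raise ValueError("N50 targets must be > 0")
        for frac in (self.q_fail_frac, self.junction_read_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        for t in self.targets:
            clen = self.genome.length_of(t.contig)
            if t.end > clen:
                raise ValueError(f"target {t.name!r} outside contig {t.contig!r}")


@dataclass
class TruthJunction:
    side_a: JunctionSide
    side_b: JunctionSide
    read_ids: set = field(default_factory=set)

    def key(self) -> tuple:
        return (self.side_a.key(), self.side_b.key())


@dataclass
class TruthSet:
    """Ground truth for one simulated run."""

    svs: list[PlantedSV]
    read_fates: dict[str, Fate]
    junctions: list[TruthJunction]

    def junction_by_position(self, contig: str, position: int, tol: int = 0):
        for j in self.junctions:
            for side in (j.side_a, j.side_b):
                if side.contig == contig and abs(side.position - position) <= tol:
                    return j
        return None


def lognormal_mu_for_n50(n50: float, sigma: float) -> float:
    """Log-normal location parameter whose length-weighted median is ``n50``.

    For lengths ~ LogNormal(mu, sigma), the length-weighted (size-biased)
    distribution is LogNormal(mu + sigma^2, sigma), so the N50 — the median
    base-weighted length — is exp(mu + sigma^2).
    """
    return math.log(n50) - sigma * sigma


def _sample_quals(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Mean read qualities: a q_fail_frac slab below Q10, the rest above."""
    from scipy.stats import truncnorm

    q = np.empty(n)
    fail = rng.random(n) < cfg.q_fail_frac
    n_fail = int(fail.sum())
    q[fail] = rng.uniform(4.0, 9.99, n_fail)
    a = (10.0 - cfg.q_mean) / cfg.q_sd
    q[~fail] = truncnorm.rvs(a, np.inf, loc=cfg.q_mean, scale=cfg.q_sd,
                             size=n - n_fail, random_state=rng)
    return q


@dataclass
class SimulatedRun:
    records: list[ReadRecord]
    segments: list[AlignmentSegment]
    truth: TruthSet


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def simulate_run(config: SimulationConfig) -> SimulatedRun:
    """Simulate one adaptive-sampling run.

    Returns the sequencing-summary records, the alignment segments, and
    the truth set. Identical configuration (including seed) gives
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    hap0, hap1 = apply_svs(config.genome, config.svs)
    haplotypes = [hap0, hap1]

    truth_junctions: dict[tuple, TruthJunction] = {}
    for hap in haplotypes:
        for dc in hap:
            for side_a, side_b in dc.junctions():
                tj = TruthJunction(side_a, side_b)
                truth_junctions.setdefault(tj.key(), tj)

    records: list[ReadRecord] = []
    segments: list[AlignmentSegment] = []
    read_fates: dict[str, Fate] = {}

    mu_off = lognormal_mu_for_n50(config.off_n50, config.sigma_off)
    mean_off = math.exp(mu_off + config.sigma_off**2 / 2)
    mu_on = lognormal_mu_for_n50(config.on_n50, config.sigma_on)
    mean_on = math.exp(mu_on + config.sigma_on**2 / 2)

    # --- off-target (ejected) reads: uniform over derived material -------
    n_off_total = 0
    for hap in haplotypes:
        for dc in hap:
            expect = config.off_target_depth / 2 * dc.length / mean_off
            n = int(rng.poisson(expect))
            if n == 0:
                continue
            starts = rng.integers(0, dc.length, n)
            lens = np.maximum(rng.lognormal(mu_off, config.sigma_off, n), 30).astype(int)
            # truncate at the end of the enclosing piece: ejected reads are
            # too short to carry useful split alignments, and never split.
            idx = np.searchsorted(dc.offsets, starts, side="right") - 1
            piece_starts = np.asarray([p.start for p in dc.pieces])
            piece_ends = np.asarray([p.end for p in dc.pieces])
            piece_fwd = np.asarray([p.strand == "+" for p in dc.pieces])
            off_in_piece = starts - dc.offsets[idx]
            avail = (piece_ends - piece_starts)[idx] - off_in_piece
            seg_len = np.minimum(lens, avail)
            fwd = piece_fwd[idx]
            ref_start = np.where(
                fwd,
                piece_starts[idx] + off_in_piece,
                piece_ends[idx] - off_in_piece - seg_len,
            )
            ref_end = ref_start + seg_len
            flip = rng.random(n) < 0.5
            strands = np.where(fwd ^ flip, "+", "-")
            quals = _sample_quals(rng, n, config)
            contig_of = np.asarray([p.contig for p in dc.pieces])[idx]
            for k in range(n):
                rid = f"off_{n_off_total:07d}"
                n_off_total += 1
                length = int(seg_len[k])
                records.append(
                    ReadRecord(rid, length, float(quals[k]), UNBLOCK_END_REASON)
                )
                read_fates[rid] = Fate.OFF_TARGET
                segments.append(
                    AlignmentSegment(
                        rid, 0, str(contig_of[k]), int(ref_start[k]),
                        int(ref_end[k]), str(strands[k]), ReadClass.OFF_TARGET,
                    )
                )

    # --- on-target (accepted) reads: start inside targeted material ------
    n_on_total = 0
    for hap in haplotypes:
        for dc in hap:
            ivals = []
            for t in config.targets:
                ivals.extend(dc.derived_intervals_of(t.contig, t.start, t.end))
            for s, e in _merge_intervals(ivals):
                span = e - s
                expect = config.on_target_depth / 2 * (span + mean_on) / mean_on
                n = int(rng.poisson(expect))
                if n == 0:
                    continue
                lens = np.maximum(
                    rng.lognormal(mu_on, config.sigma_on, n), 100
                ).astype(int)
                starts = (s - lens + rng.random(n) * (span + lens)).astype(int)
                quals = _sample_quals(rng, n, config)
                flips = rng.random(n) < 0.5
                keep_split = rng.random(n) < config.junction_read_frac
                for k in range(n):
                    x = max(0, int(starts[k]))
                    y = min(int(starts[k]) + int(lens[k]), dc.length)
                    if y - x < 50:
                        continue
                    rid = f"on_{n_on_total:07d}"
                    n_on_total += 1
                    segs = dc.map_interval(x, y)
                    if len(segs) > 1 and not keep_split[k]:
                        segs = segs[:1]
                    if len(segs) > 1:
                        # register junction support before any jitter
                        for a, b in zip(segs, segs[1:]):
                            sa = exit_side(Piece(a[0], a[1], a[2], a[3]))
                            sb = entry_side(Piece(b[0], b[1], b[2], b[3]))
                            key = TruthJunction(*canonical_sides(sa, sb)).key()
                            if key in truth_junctions:
                                truth_junctions[key].read_ids.add(rid)
                        if config.junction_jitter > 0:
                            segs = _jitter_junctions(segs, config.junction_jitter, rng)
                    if flips[k]:
                        segs = [(c, s0, e0, "+" if st == "-" else "-")
                                for c, s0, e0, st in segs[::-1]]
                    length = sum(e0 - s0 for _, s0, e0, _ in segs)
                    records.append(
                        ReadRecord(rid, length, float(quals[k]), ACCEPT_END_REASON)
                    )
                    read_fates[rid] = Fate.ON_TARGET
                    for si, (c, s0, e0, st) in enumerate(segs):
                        segments.append(
                            AlignmentSegment(rid, si, c, s0, e0, st, ReadClass.ON_TARGET)
                        )

    truth = TruthSet(
        svs=list(config.svs),
        read_fates=read_fates,
        junctions=list(truth_junctions.values()),
    )
    return SimulatedRun(records=records, segments=segments, truth=truth)


def _jitter_junctions(segs, sd: float, rng: np.random.Generator):
    """Perturb junction-facing segment ends by a little alignment noise."""
    out = [list(s) for s in segs]
    for i in range(len(out) - 1):
        a, b = out[i], out[i + 1]
        da = int(round(rng.normal(0, sd)))
        db = int(round(rng.normal(0, sd)))
        # jitter the junction-facing end of each segment, keeping it valid
        if a[3] == "+":
            a[2] = max(a[1] + 1, a[2] + da)
        else:
            a[1] = min(a[2] - 1, a[1] + da)
        if b[3] == "+":
            b[1] = min(b[2] - 1, b[1] + db)
        else:
            b[2] = max(b[1] + 1, b[2] + db)
    return [tuple(s) for s in out]


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------


def trip_quint_trip_pieces(
    contig: str, clen: int, p0: int, p1: int, p2: int, p3: int
) -> list[Piece]:
    """Carrier-haplotype pieces for a TRIP-QUINT-TRIP with inverted blocks.

    Segment copies on the carrier: S1 [p0,p1) x3, S2 [p1,p2) x5,
    S3 [p2,p3) x3 (total copy numbers 4/6/4 on a het background), arranged
    with inverted internal blocks so each boundary carries a fold-back
    style junction.
    """
    s1 = Piece(contig, p0, p1, "+")
    s2 = Piece(contig, p1, p2, "+")
    s3 = Piece(contig, p2, p3, "+")
    s1i = Piece(contig, p0, p1, "-")
    s2i = Piece(contig, p1, p2, "-")
    s3i = Piece(contig, p2, p3, "-")
    return [
        Piece(contig, 0, p0, "+"),
        s1, s2, s3,
        s3i, s2i, s1i,
        s1, s2,
        s2i,
        s2, s3,
        Piece(contig, p3, clen, "+"),
    ]


def dup_nml_dup_pieces(
    contig: str, clen: int, p0: int, p1: int, p2: int, p3: int
) -> list[Piece]:
    """Carrier pieces for a DUP-NML-DUP: both flanks tandem-duplicated."""
    return [
        Piece(contig, 0, p1, "+"),
        Piece(contig, p0, p1, "+"),
        Piece(contig, p1, p3, "+"),
        Piece(contig, p2, p3, "+"),
        Piece(contig, p3, clen, "+"),
    ]


def fixture_configs(seed: int = 0) -> dict[str, SimulationConfig]:
    """The canonical fixture runs used throughout the test surface.

    a) DUP-NML-DUP inside one target;
    b) TRIP-QUINT-TRIP with inverted blocks inside one target;
    c) inter-contig translocation with only one side targeted;
    d) an untargeted 1 Mb heterozygous deletion, visible only in the
       ejected-read background.
    """
    genome = GenomeLayout(
        [("chr1", 5_000_000), ("chr2", 5_000_000), ("chr3", 3_000_000)]
    )
    configs: dict[str, SimulationConfig] = {}

    # (a) DUP-NML-DUP: 150/200/150 kb blocks inside a 1 Mb target. A large
    # control target keeps the all-targets reference mean close to the
    # diploid level despite the extra copies in the rearranged locus.
    p = (2_200_000, 2_350_000, 2_550_000, 2_700_000)
    sv_a = PlantedSV(
        kind="composite",
        loci=[("chr1", p[0], p[3])],
        expected_cn=3,
        custom_pieces={"chr1": dup_nml_dup_pieces("chr1", 5_000_000, *p)},
        name="dup_nml_dup",
    )
    configs["dup_nml_dup"] = SimulationConfig(
        genome=genome,
        targets=[
            TargetRegion("A", "chr1", 2_000_000, 3_000_000),
            TargetRegion("B", "chr3", 500_000, 2_500_000, role=Role.CONTROL),
        ],
        svs=[sv_a],
        seed=seed,
    )

    # (b) TRIP-QUINT-TRIP: 150/200/150 kb blocks, total CN 4/6/4
    q = (1_250_000, 1_400_000, 1_600_000, 1_750_000)
    sv_b = PlantedSV(
        kind="composite",
        loci=[("chr2", q[0], q[3])],
        expected_cn=6,
        custom_pieces={"chr2": trip_quint_trip_pieces("chr2", 5_000_000, *q)},
        name="trip_quint_trip",
    )
    configs["trip_quint_trip"] = SimulationConfig(
        genome=genome,
        targets=[
            TargetRegion("C", "chr2", 1_000_000, 2_000_000),
            TargetRegion("B", "chr1", 1_000_000, 3_500_000, role=Role.CONTROL),
            TargetRegion("D", "chr3", 500_000, 2_500_000, role=Role.CONTROL),
        ],
        svs=[sv_b],
        seed=seed,
    )

    # (c) translocation: chr1:2.5M <-> chr3:1.5M, only the chr1 side targeted
    sv_c = PlantedSV(
        kind="translocation",
        loci=[("chr1", 2_500_000), ("chr3", 1_500_000)],
        name="tra_one_sided",
    )
    configs["translocation"] = SimulationConfig(
        genome=genome,
        targets=[TargetRegion("K", "chr1", 2_400_000, 2_600_000)],
        svs=[sv_c],
        seed=seed,
    )

    # (d) untargeted 1 Mb het deletion on chr2; target elsewhere
    sv_d = PlantedSV(
        kind="deletion", loci=[("chr2", 2_000_000, 3_000_000)], name="bg_del"
    )
    configs["background_deletion"] = SimulationConfig(
        genome=genome,
        targets=[TargetRegion("A", "chr1", 1_000_000, 1_500_000, role=Role.CONTROL)],
        svs=[sv_d],
        seed=seed,
    )
    return configs


def background_scan_demo_config(kind: str = "deletion", seed: int = 0) -> SimulationConfig:
    """Canonical conditions for demonstrating the ejected-read CNV scan.

    A 3-contig toy genome with ~4.5x off-target depth and one planted
    heterozygous 1 Mb event outside all targets. The contigs (30/20/15 Mb)
    keep the event a small fraction of its chromosome, as in real genomes,
    so the per-chromosome reference mean is essentially unbiased and the
    expected call level sits at the theoretical -1 (loss) or +0.58 (gain).
    """
    genome = GenomeLayout(
        [("chr1", 30_000_000), ("chr2", 20_000_000), ("chr3", 15_000_000)]
    )
    if kind == "deletion":
        sv = PlantedSV(kind="deletion", loci=[("chr2", 8_000_000, 9_000_000)])
    elif kind == "gain":
        sv = PlantedSV(kind="duplication", loci=[("chr2", 8_000_000, 9_000_000)])
    else:
        raise ValueError(f"kind must be 'deletion' or 'gain', got {kind!r}")
    return SimulationConfig(
        genome=genome,
        targets=[TargetRegion("A", "chr1", 1_000_000, 1_500_000, role=Role.CONTROL)],
        svs=[sv],
        off_target_depth=4.5,
        seed=seed,
    )


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Simulate and write the canonical fixtures as text files.

    Each fixture directory gets ``summary.tsv``, ``alignments.tsv`` and
    ``truth.json``. The same seed always writes identical files.
    """
    out_dir = Path(out_dir)
    written: dict[str, Path] = {}
    for name, cfg in fixture_configs(seed).items():
        run = simulate_run(cfg)
        d = out_dir / name
        os.makedirs(d, exist_ok=True)
        core_io.write_sequencing_summary(run.records, d / "summary.tsv")
        core_io.write_alignments_tsv(run.segments, d / "alignments.tsv")
        truth = {
            "svs": [
                {
                    "name": sv.name,
                    "kind": sv.kind,
                    "loci": [list(l) for l in sv.loci],
                    "genotype": sv.genotype,
                    "expected_cn": sv.expected_cn,
                }
                for sv in run.truth.svs
            ],
            "junctions": [
                {
                    "side_a": list(j.side_a.key()),
                    "side_b": list(j.side_b.key()),
                    "n_reads": len(j.read_ids),
                }
                for j in run.truth.junctions
            ],
        }
        with open(d / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        written[name] = d
    return written
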