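"""Shared domain types for the adaptive-sampling SV validation pipeline.

Coordinates are 0-based, half-open (BED convention) everywhere inside the
package. Human-facing "chr:start-end" strings in the 1-based inclusive
dialect are converted on parse and on display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class Role(str, Enum):
    """Why a region was targeted: a control locus or a rearrangement locus."""

    CONTROL = "control"
    REARRANGEMENT = "rearrangement"


class Fate(str, Enum):
    """Adaptive-sampling fate of a read: allowed to finish, or ejected."""

    ON_TARGET = "on_target"
    OFF_TARGET = "off_target"


class ReadClass(str, Enum):
    ON_TARGET = "on_target"
    OFF_TARGET = "off_target"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


#: MinKNOW end_reason marking an adaptive-sampling ejection.
UNBLOCK_END_REASON = "data_service_unblock_mux_change"


@dataclass(frozen=True)
class TargetRegion:
    """A named genomic interval supplied to adaptive sampling.

    ``start``/``end`` are 0-based half-open. ``assembly`` is a free-text
    label (e.g. "GRCh38", "T2T-CHM13"); no liftover is ever attempted.
    """

    name: str
    contig: str
    start: int
    end: int
    assembly: str = "GRCh38"
    role: Role = Role.REARRANGEMENT

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError(f"region {self.name!r}: empty contig")
        if self.end <= self.start:
            raise ValueError(
                f"region {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_inclusive_string(self) -> str:
        """Render as a 1-based inclusive coordinate string with separators."""
        return f"{self.contig}:{self.start + 1:,}-{self.end:,}"


@dataclass
class GenomeLayout:
    """Ordered contig table describing a genome, plus sample sex.

    Sex matters because male chrX carries a single copy: it is excluded
    from autosomal normalisation and given baseline copy number 1.
    """

    contigs: Sequence[tuple[str, int]]
    sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        names = [c for c, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names in genome layout")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name!r}: non-positive length {length}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    def length_of(self, contig: str) -> int:
        for name, length in self.contigs:
            if name == contig:
                return length
        raise KeyError(f"contig {contig!r} not in genome layout")

    def contig_names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    def is_x(self, contig: str) -> bool:
        return contig.lower().lstrip("chr") == "x" or contig.lower() in ("chrx", "x")

    def baseline_cn(self, contig: str) -> int:
        """Expected total copy number: 2, or 1 on male chrX."""
        if self.sex == Sex.MALE and self.is_x(contig):
            return 1
        return 2


@dataclass
class ReadRecord:
    """One read's summary-sheet metadata (MinKNOW sequencing summary row)."""

    read_id: str
    length: int
    mean_q: float
    end_reason: str
    fate: Optional[Fate] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"read {self.read_id!r}: negative length")


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned block of a read (primary or supplementary alignment).

    ``segment_index`` orders the blocks along the read (query offset order),
    so consecutive pairs delimit candidate breakpoint junctions.
    """

    read_id: str
    segment_index: int
    contig: str
    start: int
    end: int
    strand: str
    read_class: ReadClass = ReadClass.UNKNOWN

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.read_id!r}[{self.segment_index}]: end <= start"
            )
        if self.segment_index < 0:
            raise ValueError("segment_index must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class DepthProfile:
    """Per-bin mean depth over a binned interval set.

    Bins tile each parent interval without overlap; the last bin of an
    interval may be short. ``read_class`` records which reads contributed
    (all passing reads, or ejected reads only).
    """

    bins: list[tuple[str, int, int]]
    depth: "list[float]"
    bin_size: int
    read_class: str = "all_passing"

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.depth):
            raise ValueError("bins and depth lengths differ")

    def __len__(self) -> int:
        return len(self.bins)


class SegmentStatus(str, Enum):
    LOSS = "loss"
    NEUTRAL = "neutral"
    GAIN = "gain"


@dataclass
class CNSegment:
    """A copy-number segment called from the binned log2 track."""

    contig: str
    start: int
    end: int
    mean_log2: float
    cn_estimate: int
    n_bins: int
    status: SegmentStatus
    annotation: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def cn_from_log2(mean_log2: float, baseline: int = 2) -> int:
    """Integer copy number implied by a mean log2 ratio against ``baseline``."""
    if math.isinf(mean_log2) and mean_log2 < 0:
        return 0
    return max(0, round(baseline * 2.0**mean_log2))


class Orientation(str, Enum):
    """Which reference side of a junction a read runs into.

    ``TAIL`` means the read leaves through the right (3') end of the
    segment on the reference; ``HEAD`` means it enters at the left (5') end.
    """

    HEAD = "head"
    TAIL = "tail"


class JunctionType(str, Enum):
    DEL_LIKE = "DEL-like"
    DUP_LIKE = "DUP-like"
    INV_LIKE = "INV-like"
    TRA = "TRA"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class JunctionSide:
    contig: str
    position: int
    orientation: Orientation

    def key(self) -> tuple:
        return (self.contig, self.position, self.orientation.value)


@dataclass
class Junction:
    """A clustered breakpoint junction supported by split reads."""

    side_a: JunctionSide
    side_b: JunctionSide
    support: int
    span_reads: list[str] = field(default_factory=list)
    type: JunctionType = JunctionType.AMBIGUOUS
    position_range_a: tuple[int, int] = (0, 0)
    position_range_b: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("junction support must be >= 1")


class Verdict(str, Enum):
    CONFIRMED_NUCLEOTIDE = "confirmed_nucleotide"
    SUPPORTED_DEPTH_ONLY = "supported_depth_only"
    NOT_CONFIRMED = "not_confirmed"
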