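"""Readers and writers for the external formats shared by every stage.

Supported inputs
----------------
* target regions: BED, or a table of "chr:start-end" coordinate strings in
  the 1-based inclusive dialect used in clinical reports (thousands
  separators are tolerated and stripped);
* genomes: FASTA (indexed through :mod:`pyfaidx`) or a two-column
  contig/length table;
* sequencing summaries: MinKNOW-style TSV with an ``end_reason`` column;
* alignments: SAM/BAM (primary + supplementary records, via :mod:`pysam`)
  or a documented plain TSV dialect so the whole pipeline stays testable
  with text fixtures.

Outputs are bedGraph depth/log2 tracks, a minimal VCF-like calls file and
a tab-separated report.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .types import (
    AlignmentSegment,
    CNSegment,
    DepthProfile,
    GenomeLayout,
    Junction,
    ReadClass,
    ReadRecord,
    Role,
    Sex,
    TargetRegion,
)

logger = logging.getLogger(__name__)

_COORD_RE = re.compile(r"^(?P<contig>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")

#: Accepted values for the ``convention`` argument of :func:`read_regions`.
CONVENTIONS = ("bed_0_half_open", "table_1_inclusive")


class ParseError(ValueError):
    """A malformed line in an input file; carries the line number."""


def parse_coordinate_string(
    text: str,
    convention: str = "table_1_inclusive",
    name: str = "",
    assembly: str = "GRCh38",
    role: Role = Role.REARRANGEMENT,
) -> TargetRegion:
    """Parse one "chr:start-end" string into a :class:`TargetRegion`.

    ``table_1_inclusive`` treats the coordinates as 1-based inclusive
    (``start-1`` converts to the internal half-open convention);
    ``bed_0_half_open`` takes them verbatim. Thousands separators are
    stripped.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    m = _COORD_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse coordinate string {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if convention == "table_1_inclusive":
        start -= 1
    if end <= start:
        raise ParseError(f"coordinate string {text!r}: end <= start after conversion")
    return TargetRegion(
        name=name or "R1",
        contig=m.group("contig"),
        start=start,
        end=end,
        assembly=assembly,
        role=role,
    )


def read_regions(
    path: str | Path,
    convention: str = "bed_0_half_open",
) -> list[TargetRegion]:
    """Read target regions from a BED file or a coordinate-string table.

    Each non-comment line is either BED (``contig<TAB>start<TAB>end[<TAB>name]``)
    or ``[name<TAB>]chr:start-end[<TAB>assembly]``. Names are auto-assigned
    ("R1", "R2", ...) when absent. All regions come back in the internal
    0-based half-open convention.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    path = Path(path)
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            auto_name = f"R{len(regions) + 1}"
            try:
                region = _parse_region_fields(fields, convention, auto_name)
            except ParseError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            regions.append(region)
    return regions


def _parse_region_fields(
    fields: Sequence[str], convention: str, auto_name: str
) -> TargetRegion:
    if len(fields) >= 3 and fields[1].replace(",", "").isdigit() and fields[2].replace(
        ",", ""
    ).isdigit():
        # BED-like: contig start end [name]
        start = int(fields[1].replace(",", ""))
        end = int(fields[2].replace(",", ""))
        if convention == "table_1_inclusive":
            start -= 1
        name = fields[3] if len(fields) >= 4 else auto_name
        return TargetRegion(name=name, contig=fields[0], start=start, end=end)
    # coordinate-string dialect: [name] chr:start-end [assembly]
    if _COORD_RE.match(fields[0]):
        coord, name, rest = fields[0], auto_name, fields[1:]
    elif len(fields) >= 2 and _COORD_RE.match(fields[1]):
        name, coord, rest = fields[0], fields[1], fields[2:]
    else:
        raise ParseError(f"unrecognised region line: {fields!r}")
    assembly = rest[0] if rest else "GRCh38"
    return parse_coordinate_string(coord, convention, name=name, assembly=assembly)


def read_genome_layout(path: str | Path, sex: Sex = Sex.UNKNOWN) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from a FASTA or a contig-length table."""
    path = Path(path)
    head = open(path).read(1)
    if head == ">":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        contigs = [(name, len(fa[name])) for name in fa.keys()]
        return GenomeLayout(contigs=contigs, sex=sex)
    contigs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}, line {lineno}: expected contig<TAB>length")
            contigs.append((fields[0], int(fields[1].replace(",", ""))))
    return GenomeLayout(contigs=contigs, sex=sex)


def extract_target_fasta(
    genome_fasta: str | Path,
    regions: Sequence[TargetRegion],
    out_path: str | Path,
) -> Path:
    """Cut region subsequences out of a genome FASTA.

    One output record per region, in input order, with id
    ``name:contig:start-end`` and sequence length equal to the region
    length. Case is preserved from the source.
    """
    import pyfaidx

    fa = pyfaidx.Fasta(str(genome_fasta))
    out_path = Path(out_path)
    with open(out_path, "w") as out:
        for region in regions:
            if region.contig not in fa:
                raise KeyError(f"region {region.name!r}: contig {region.contig!r} not in FASTA")
            contig_len = len(fa[region.contig])
            if region.end > contig_len:
                raise ValueError(
                    f"region {region.name!r}: end {region.end} beyond contig "
                    f"{region.contig!r} length {contig_len}"
                )
            seq = fa[region.contig][region.start : region.end].seq
            out.write(f">{region.name}:{region.contig}:{region.start}-{region.end}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")
    return out_path


# ---------------------------------------------------------------------------
# sequencing summary
# ---------------------------------------------------------------------------

#: Default MinKNOW column names; override via ``columns=`` for other dialects.
SUMMARY_COLUMNS = {
    "read_id": "read_id",
    "length": "sequence_length_template",
    "mean_q": "mean_qscore_template",
    "end_reason": "end_reason",
}


def read_sequencing_summary(
    path: str | Path,
    columns: Optional[dict[str, str]] = None,
) -> list[ReadRecord]:
    """Read a MinKNOW-style sequencing summary TSV into ReadRecords.

    The fate field is left unset; classification is a separate step.
    Raises a schema error listing the columns found if a mandatory column
    is missing.
    """
    import pandas as pd

    cols = dict(SUMMARY_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype={cols["read_id"]: str, cols["end_reason"]: str})
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(
            f"sequencing summary {path}: missing column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return [
        ReadRecord(
            read_id=row[cols["read_id"]],
            length=int(row[cols["length"]]),
            mean_q=float(row[cols["mean_q"]]),
            end_reason=str(row[cols["end_reason"]]),
        )
        for row in df.to_dict("records")
    ]


def write_sequencing_summary(records: Iterable[ReadRecord], path: str | Path) -> Path:
    """Write ReadRecords as a MinKNOW-style summary TSV (round-trips with
    :func:`read_sequencing_summary`)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsequence_length_template\tmean_qscore_template\tend_reason\n"
        )
        for r in records:
            fh.write(f"{r.read_id}\t{r.length}\t{r.mean_q:.2f}\t{r.end_reason}\n")
    return path


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operations that consume the reference.
_REF_OPS = frozenset("MDN=X")
#: CIGAR operations that consume the query.
_QUERY_OPS = frozenset("MIS=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string (M/=/X/D/N)."""
    span = 0
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r}")
        pos = m.end()
        if m.group(2) in _REF_OPS:
            span += int(m.group(1))
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return span


def cigar_query_start(cigar: str, reverse: bool) -> int:
    """Offset of the aligned block from the start of the *original* read.

    For a forward alignment this is the leading clip length; for a reverse
    alignment the read starts at the other end, so it is the trailing clip.
    Used to order split-alignment segments along the read.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops:
        return 0
    if reverse:
        ops = ops[::-1]
    offset = 0
    for n, op in ops:
        if op in ("S", "H"):
            offset += int(n)
        else:
            break
    return offset


ALIGNMENT_TSV_HEADER = "read_id\tsegment_index\tcontig\tstart\tend\tstrand\tread_class"


def read_alignments(path: str | Path) -> list[AlignmentSegment]:
    """Read alignment segments from SAM/BAM or the plain TSV dialect.

    SAM/BAM: primary and supplementary records are converted to one
    segment each; reference spans come from the CIGAR (M/=/X/D/N consume
    reference); segments of one read are ordered by query offset.
    Secondary and unmapped records are skipped (counts logged).

    TSV dialect: ``read_id  segment_index  contig  start  end  strand
    read_class`` with a header line.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if path.suffix in (".sam", ".bam", ".cram") or magic[:2] == b"\x1f\x8b" or magic == b"BAM\x01":
        return _read_alignments_pysam(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@") or "\t" in first and first.split("\t")[0] not in (
        "read_id",
    ) and len(first.split("\t")) >= 11:
        return _read_alignments_pysam(path)
    return _read_alignments_tsv(path)


def _read_alignments_pysam(path: Path) -> list[AlignmentSegment]:
    import pysam

    mode = "rb" if path.suffix == ".bam" else "r"
    raw: list[tuple[str, int, str, int, int, str]] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary:
                continue
            cigar = rec.cigarstring or ""
            span = cigar_reference_span(cigar) if cigar else (rec.query_length or 0)
            qoff = cigar_query_start(cigar, rec.is_reverse) if cigar else 0
            raw.append(
                (
                    rec.query_name,
                    qoff,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_start + span,
                    "-" if rec.is_reverse else "+",
                )
            )
    if n_unmapped:
        logger.info("skipped %d unmapped records in %s", n_unmapped, path)
    # order each read's segments by query offset, stable on file order
    by_read: dict[str, list[tuple]] = {}
    for rec in raw:
        by_read.setdefault(rec[0], []).append(rec)
    segments: list[AlignmentSegment] = []
    for read_id, recs in by_read.items():
        recs.sort(key=lambda r: r[1])
        for idx, (rid, _qoff, contig, start, end, strand) in enumerate(recs):
            segments.append(
                AlignmentSegment(
                    read_id=rid,
                    segment_index=idx,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return segments


def _read_alignments_tsv(path: Path) -> list[AlignmentSegment]:
    segments: list[AlignmentSegment] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != ALIGNMENT_TSV_HEADER:
            raise ValueError(
                f"alignment TSV {path}: unexpected header {header!r}; "
                f"expected {ALIGNMENT_TSV_HEADER!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(f"{path}, line {lineno}: expected 7 fields")
            segments.append(
                AlignmentSegment(
                    read_id=fields[0],
                    segment_index=int(fields[1]),
                    contig=fields[2],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[5],
                    read_class=ReadClass(fields[6]),
                )
            )
    return segments


def write_alignments_tsv(segments: Iterable[AlignmentSegment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(ALIGNMENT_TSV_HEADER + "\n")
        for s in segments:
            fh.write(
                f"{s.read_id}\t{s.segment_index}\t{s.contig}\t{s.start}\t{s.end}"
                f"\t{s.strand}\t{s.read_class.value}\n"
            )
    return path


# ---------------------------------------------------------------------------
# tracks and calls
# ---------------------------------------------------------------------------


def write_bedgraph(profile: DepthProfile, path: str | Path, values=None) -> Path:
    """Write a DepthProfile (or a parallel value vector) as bedGraph."""
    path = Path(path)
    vals = profile.depth if values is None else values
    with open(path, "w") as fh:
        for (contig, start, end), v in zip(profile.bins, vals):
            fh.write(f"{contig}\t{start}\t{end}\t{v:.6g}\n")
    return path


def read_bedgraph(path: str | Path, bin_size: Optional[int] = None) -> DepthProfile:
    """Read a bedGraph track back into a DepthProfile."""
    bins: list[tuple[str, int, int]] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            contig, start, end, v = line.split("\t")
            bins.append((contig, int(start), int(end)))
            vals.append(float(v))
    if bin_size is None:
        bin_size = max((e - s for _, s, e in bins), default=1)
    return DepthProfile(bins=bins, depth=vals, bin_size=bin_size)


def write_tracks_and_calls(
    out_dir: str | Path,
    genome: GenomeLayout,
    profiles: Optional[dict[str, DepthProfile]] = None,
    segments: Optional[Sequence[CNSegment]] = None,
    junctions: Optional[Sequence[Junction]] = None,
) -> dict[str, Path]:
    """Write depth/log2 tracks, a minimal VCF-like calls file and a TSV report.

    Ordering is deterministic: contig order of the genome layout, then
    start coordinate. Re-writing re-read output is byte-identical.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    contig_rank = {name: i for i, name in enumerate(genome.contig_names())}
    written: dict[str, Path] = {}

    for name, profile in (profiles or {}).items():
        order = sorted(
            range(len(profile.bins)),
            key=lambda i: (contig_rank.get(profile.bins[i][0], 1 << 30), profile.bins[i][1]),
        )
        p = out_dir / f"{name}.bedgraph"
        with open(p, "w") as fh:
            for i in order:
                contig, start, end = profile.bins[i]
                fh.write(f"{contig}\t{start}\t{end}\t{profile.depth[i]:.6g}\n")
        written[name] = p

    segs = sorted(
        segments or [], key=lambda s: (contig_rank.get(s.contig, 1 << 30), s.start)
    )
    juncs = sorted(
        junctions or [],
        key=lambda j: (
            contig_rank.get(j.side_a.contig, 1 << 30),
            j.side_a.position,
            contig_rank.get(j.side_b.contig, 1 << 30),
            j.side_b.position,
        ),
    )

    calls_path = out_dir / "calls.vcf"
    with open(calls_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number estimate">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Spanning reads">\n')
        fh.write('##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner contig">\n')
        fh.write('##INFO=<ID=POS2,Number=1,Type=Integer,Description="Partner position">\n')
        for name, length in genome.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        n = 0
        for s in segs:
            if s.status.value == "neutral":
                continue
            n += 1
            svtype = "DEL" if s.status.value == "loss" else "DUP"
            fh.write(
                f"{s.contig}\t{s.start + 1}\tcn{n}\tN\t<{svtype}>\t.\tPASS\t"
                f"END={s.end};SVTYPE={svtype};CN={s.cn_estimate}\n"
            )
        for j in juncs:
            n += 1
            fh.write(
                f"{j.side_a.contig}\t{j.side_a.position + 1}\tjct{n}\tN\t<{j.type.value.split('-')[0]}>\t.\tPASS\t"
                f"SVTYPE={j.type.value};CHR2={j.side_b.contig};POS2={j.side_b.position + 1};"
                f"SUPPORT={j.support}\n"
            )
    written["calls"] = calls_path

    report_path = out_dir / "report.tsv"
    with open(report_path, "w") as fh:
        fh.write("kind\tcontig\tstart\tend\tstatus\tmean_log2\tcn\tsupport\tpartner\n")
        for s in segs:
            fh.write(
                f"cn_segment\t{s.contig}\t{s.start}\t{s.end}\t{s.status.value}\t"
                f"{s.mean_log2:.4f}\t{s.cn_estimate}\t.\t.\n"
            )
        for j in juncs:
            partner = f"{j.side_b.contig}:{j.side_b.position}"
            fh.write(
                f"junction\t{j.side_a.contig}\t{j.side_a.position}\t{j.side_a.position}\t"
                f"{j.type.value}\t.\t.\t{j.support}\t{partner}\n"
            )
    written["report"] = report_path
    return written
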