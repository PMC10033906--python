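"""Junction extraction from RNA-seq alignment CIGAR skipped regions.

Every ``N`` CIGAR operator in a usable alignment yields one junction
observation.  The anchor on each side of an ``N`` is the span of
reference-consuming operators (match / mismatch / deletion) between the read
end (or the adjacent ``N``) and the skip; insertions and clips contribute
nothing.  Observations are aggregated per (contig, intron, strand); the
union of supporting anchors determines the thickStart / thickEnd of the
BED12 feature, and a junction passes the anchor filter when its maximal
anchor on each side reaches the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

from .reference_model import GenomicInterval

# reference-consuming CIGAR ops that count toward anchors
_ANCHOR_OPS = {0, 2, 7, 8}  # M, D, =, X
_REF_SKIP = 3  # N
_REF_OPS = _ANCHOR_OPS | {_REF_SKIP}

DEFAULT_MIN_ANCHOR = 8
DEFAULT_MIN_INTRON = 70
DEFAULT_MAX_INTRON = 500_000


@dataclass(frozen=True)
class JunctionObservation:
    contig: str
    intron_start: int
    intron_end: int
    left_anchor: int
    right_anchor: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.intron_end - self.intron_start < 1:
            raise ValueError("intron must span at least one base")
        if self.left_anchor < 1 or self.right_anchor < 1:
            raise ValueError("anchors must be >= 1")


@dataclass
class Junction:
    """An aggregated intron with read support and outermost anchor bounds."""

    contig: str
    intron_start: int
    intron_end: int
    strand: str
    score: int
    thick_start: int
    thick_end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (
            self.thick_start <= self.intron_start < self.intron_end <= self.thick_end
        ):
            raise ValueError("thick bounds must bracket the intron")
        if self.score < 1:
            raise ValueError("score must be >= 1")
        if not self.name:
            self.name = junction_name(
                self.contig, self.intron_start, self.intron_end, self.strand
            )

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.intron_start, self.intron_end, self.strand)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.intron_start, self.intron_end, self.strand
        )


def junction_name(contig: str, start: int, end: int, strand: str) -> str:
    """Deterministic, coordinate-derived junction name.

    Coordinate-derived names keep outputs stable under region-restricted
    extraction (serial numbering would not).
    """
    return f"JUNC:{contig}:{start}-{end}:{strand}"


def read_to_junctions(record, strand: str = "?") -> list[JunctionObservation]:
    """Decompose one alignment record into junction observations.

    Unmapped, secondary, and supplementary records yield ``[]``.  A record
    whose CIGAR places an ``N`` at either extremity (zero anchor) is skipped
    with a warning.
    """
    if record.is_unmapped or record.is_secondary or record.is_supplementary:
        return []
    cigar = record.cigartuples
    if not cigar:
        return []
    # segments: alternating anchor spans and N lengths, starting/ending with anchor
    segments: list[int] = [0]
    skips: list[int] = []
    for op, length in cigar:
        if op == _REF_SKIP:
            skips.append(length)
            segments.append(0)
        elif op in _ANCHOR_OPS:
            segments[-1] += length
    if not skips:
        return []
    if any(anchor == 0 for anchor in segments):
        warnings.warn(
            f"read {record.query_name}: N operator at read extremity or "
            "abutting another N; record skipped",
            stacklevel=2,
        )
        return []
    observations = []
    ref_pos = record.reference_start
    contig = record.reference_name
    i = 0  # index into skips
    pos = ref_pos + segments[0]
    for i, skip in enumerate(skips):
        observations.append(
            JunctionObservation(
                contig=contig,
                intron_start=pos,
                intron_end=pos + skip,
                left_anchor=segments[i],
                right_anchor=segments[i + 1],
                strand=strand,
            )
        )
        pos += skip + segments[i + 1]
    return observations


def infer_strand(record, strandness_mode: int) -> str:
    """Infer the transcription strand of a read.

    mode 0: unstranded; use the aligner's XS-style tag if present, else "?".
    mode 1: first-strand / RF; transcription strand is opposite read 1's
            orientation (and equal to read 2's).
    mode 2: second-strand / FR; the reverse mapping.
    Single-end reads are treated as read 1.
    """
    if strandness_mode not in (0, 1, 2):
        raise ValueError(f"strandness mode must be 0, 1, or 2, got {strandness_mode}")
    if strandness_mode == 0:
        try:
            return record.get_tag("XS")
        except KeyError:
            return "?"
    is_read2 = record.is_paired and record.is_read2
    orientation = "-" if record.is_reverse else "+"
    if strandness_mode == 1:  # RF
        return orientation if is_read2 else ("-" if orientation == "+" else "+")
    return orientation if not is_read2 else ("-" if orientation == "+" else "+")


def aggregate_and_filter(
    observations: Iterable[JunctionObservation],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_intron: int = DEFAULT_MAX_INTRON,
) -> list[Junction]:
    """Group observations into junctions and apply anchor/intron filters.

    A junction is kept iff its maximal left anchor and maximal right anchor
    (union rule across supporting reads) both reach ``min_anchor`` and the
    intron length lies in [min_intron, max_intron].  Output is
    coordinate-sorted.
    """
    if min_intron > max_intron:
        raise ValueError("min_intron must be <= max_intron")
    groups: dict[tuple[str, int, int, str], list[JunctionObservation]] = {}
    for obs in observations:
        key = (obs.contig, obs.intron_start, obs.intron_end, obs.strand)
        groups.setdefault(key, []).append(obs)
    junctions = []
    for (contig, start, end, strand), obs_list in groups.items():
        if not (min_intron <= end - start <= max_intron):
            continue
        max_left = max(o.left_anchor for o in obs_list)
        max_right = max(o.right_anchor for o in obs_list)
        if max_left < min_anchor or max_right < min_anchor:
            continue
        junctions.append(
            Junction(
                contig=contig,
                intron_start=start,
                intron_end=end,
                strand=strand,
                score=len(obs_list),
                thick_start=start - max_left,
                thick_end=end + max_right,
            )
        )
    junctions.sort(
        key=lambda j: (j.contig, j.intron_start, j.intron_end, j.strand)
    )
    return junctions


def _parse_region(region: str) -> GenomicInterval:
    contig, _, span = region.partition(":")
    if span:
        start_s, _, stop_s = span.partition("-")
        return GenomicInterval(contig, int(start_s), int(stop_s))
    return GenomicInterval(contig, 0, 2**62)


def extract_junctions(
    alignment: str | Path,
    strandness: int = 0,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_intron: int = DEFAULT_MAX_INTRON,
    region: Optional[str | GenomicInterval] = None,
    include_duplicates: bool = False,
) -> list[Junction]:
    """Extract junctions from a SAM/BAM/CRAM file.

    Duplicate-flagged and QC-fail reads are excluded unless
    ``include_duplicates``.  With ``region``, the result is the
    coordinate-restricted subset (junctions whose intron overlaps the
    region) of whole-file extraction.
    """
    import pysam

    observations: list[JunctionObservation] = []
    save = pysam.set_verbosity(0)
    with pysam.AlignmentFile(str(alignment), check_sq=False) as af:
        pysam.set_verbosity(save)
        for record in af.fetch(until_eof=True):
            if not include_duplicates and (record.is_duplicate or record.is_qcfail):
                continue
            strand = infer_strand(record, strandness)
            observations.extend(read_to_junctions(record, strand=strand))
    junctions = aggregate_and_filter(
        observations,
        min_anchor=min_anchor,
        min_intron=min_intron,
        max_intron=max_intron,
    )
    if region is not None:
        if isinstance(region, str):
            region = _parse_region(region)
        junctions = [j for j in junctions if j.interval.overlaps(region)]
    return junctions


def write_bed12(junctions: Iterable[Junction], out: TextIO) -> None:
    """Write junctions as BED12: blocks are the maximal anchors."""
    for j in junctions:
        block1 = j.intron_start - j.thick_start
        block2 = j.thick_end - j.intron_end
        out.write(
            "\t".join(
                [
                    j.contig,
                    str(j.thick_start),
                    str(j.thick_end),
                    j.name,
                    str(j.score),
                    j.strand,
                    str(j.thick_start),
                    str(j.thick_end),
                    "255,0,0",
                    "2",
                    f"{block1},{block2}",
                    f"0,{j.intron_end - j.thick_start}",
                ]
            )
            + "\n"
        )


def read_bed12(source: str | Path | Iterable[str]) -> list[Junction]:
    """Read junctions from BED12 in the extract dialect."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_bed12(fh)
    junctions = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"malformed BED12 row {lineno}: expected 12 fields")
        contig = fields[0]
        chrom_start, chrom_end = int(fields[1]), int(fields[2])
        name, score, strand = fields[3], int(fields[4]), fields[5]
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        if len(block_sizes) != 2:
            raise ValueError(f"malformed BED12 row {lineno}: expected 2 blocks")
        junctions.append(
            Junction(
                contig=contig,
                intron_start=chrom_start + block_sizes[0],
                intron_end=chrom_end - block_sizes[1],
                strand=strand,
                score=score,
                thick_start=chrom_start,
                thick_end=chrom_end,
                name=name,
            )
        )
    return junctions
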