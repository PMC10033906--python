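"""Junction annotation against a reference transcriptome.

Junction types partition all observed junctions:

========  ==========================================================
DA        both sites known and the donor-acceptor pair is annotated
NDA       both sites known but never annotated in combination
D         only the donor known
A         only the acceptor known
N         neither site known
========  ==========================================================

The donor is the 5' intron boundary with respect to the transcribed strand
and the acceptor the 3' boundary.  Site matching is exact to the base.
Skipped counts use distinct site positions (not per-transcript sums) over
the transcripts of each overlapping gene; with multiple overlapping genes,
the per-gene maximum is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, TextIO

import pandas as pd

from .junctions_extract import Junction
from .reference_model import (
    GenomeSequence,
    GenomicInterval,
    TranscriptomeIndex,
    reverse_complement,
)

JUNCTION_TYPES = ("DA", "NDA", "D", "A", "N")
# for resolving unknown-strand junctions: higher class wins, ties go to "+"
_TYPE_RANK = {"DA": 4, "NDA": 3, "D": 2, "A": 2, "N": 1}

ANNOTATION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "splice_site",
    "acceptors_skipped",
    "donors_skipped",
    "exons_skipped",
    "anchor",
    "known_donor",
    "known_acceptor",
    "known_junction",
    "genes",
    "transcripts",
]


@dataclass(frozen=True)
class AnnotatedJunction:
    junction: Junction
    strand: str  # resolved strand (junction.strand may be "?")
    known_donor: bool
    known_acceptor: bool
    known_junction: bool
    junction_type: str
    donors_skipped: int
    acceptors_skipped: int
    exons_skipped: int
    splice_site: str
    transcripts: tuple[str, ...]
    genes: tuple[str, ...]

    @property
    def interval(self) -> GenomicInterval:
        return self.junction.interval


def _site_flags(
    junction: Junction, strand: str, index: TranscriptomeIndex
) -> tuple[bool, bool, bool]:
    contig, start, end = junction.contig, junction.intron_start, junction.intron_end
    if strand == "+":
        donor, acceptor = start, end
    else:
        donor, acceptor = end, start
    known_donor = (contig, donor, strand) in index.donors
    known_acceptor = (contig, acceptor, strand) in index.acceptors
    known_junction = (contig, start, end, strand) in index.known_introns
    return known_donor, known_acceptor, known_junction


def _junction_type(kd: bool, ka: bool, kj: bool) -> str:
    if kj:
        return "DA"
    if kd and ka:
        return "NDA"
    if kd:
        return "D"
    if ka:
        return "A"
    return "N"


def _skipped_counts(
    junction: Junction, index: TranscriptomeIndex
) -> tuple[int, int, int, tuple[str, ...], tuple[str, ...]]:
    """Distinct skipped donors/acceptors/exons, maximized over genes."""
    interval = junction.interval
    overlapping = index.overlapping_transcripts(
        GenomicInterval(interval.contig, interval.start, interval.end)
    )
    genes: dict[str, list] = {}
    for tx in overlapping:
        genes.setdefault(tx.gene_id, []).append(tx)
    donors_max = acceptors_max = exons_max = 0
    for gene_txs in genes.values():
        donors: set[int] = set()
        acceptors: set[int] = set()
        exons: set[tuple[int, int]] = set()
        for tx in gene_txs:
            for intron in tx.introns():
                d, a = (
                    (intron.start, intron.end)
                    if tx.strand == "+"
                    else (intron.end, intron.start)
                )
                if interval.start < d < interval.end:
                    donors.add(d)
                if interval.start < a < interval.end:
                    acceptors.add(a)
            for exon in tx.exons:
                if exon.start >= interval.start and exon.end <= interval.end:
                    exons.add((exon.start, exon.end))
        donors_max = max(donors_max, len(donors))
        acceptors_max = max(acceptors_max, len(acceptors))
        exons_max = max(exons_max, len(exons))
    tx_ids = tuple(sorted(tx.transcript_id for tx in overlapping))
    gene_names = tuple(sorted({index.gene_names[g] for g in genes}))
    return donors_max, acceptors_max, exons_max, tx_ids, gene_names


def splice_site_sequence(
    junction: Junction, genome: GenomeSequence, strand: Optional[str] = None
) -> str:
    """Donor and acceptor dinucleotides, e.g. ``"GT-AG"``.

    The first two intronic bases at the donor and the last two at the
    acceptor, reverse-complemented on the - strand, joined donor-to-acceptor.
    """
    strand = strand or junction.strand
    start, end = junction.intron_start, junction.intron_end
    if end - start < 4:
        raise ValueError("intron too short for splice-site motif")
    left = genome.fetch(junction.contig, start, start + 2)
    right = genome.fetch(junction.contig, end - 2, end)
    if strand == "-":
        return f"{reverse_complement(right)}-{reverse_complement(left)}"
    return f"{left}-{right}"


def classify_junction(
    junction: Junction,
    index: TranscriptomeIndex,
    genome: Optional[GenomeSequence] = None,
) -> AnnotatedJunction:
    """Annotate one junction: site flags, type, skipped counts, motif, genes.

    Unknown-strand junctions are evaluated on both strands and the strand
    yielding the higher class (DA > NDA > D = A > N) is adopted, ties to +.
    """
    if junction.contig not in index._trees:
        warnings.warn(
            f"junction contig {junction.contig!r} absent from annotation",
            stacklevel=2,
        )
    candidates = [junction.strand] if junction.strand in ("+", "-") else ["+", "-"]
    best = None
    for strand in candidates:
        kd, ka, kj = _site_flags(junction, strand, index)
        jtype = _junction_type(kd, ka, kj)
        entry = (strand, kd, ka, kj, jtype)
        if best is None or _TYPE_RANK[jtype] > _TYPE_RANK[best[4]]:
            best = entry
    strand, kd, ka, kj, jtype = best
    donors, acceptors, exons, tx_ids, gene_names = _skipped_counts(junction, index)
    motif = ""
    if genome is not None and junction.contig in genome.contigs:
        motif = splice_site_sequence(junction, genome, strand=strand)
    return AnnotatedJunction(
        junction=junction,
        strand=strand,
        known_donor=kd,
        known_acceptor=ka,
        known_junction=kj,
        junction_type=jtype,
        donors_skipped=donors,
        acceptors_skipped=acceptors,
        exons_skipped=exons,
        splice_site=motif,
        transcripts=tx_ids,
        genes=gene_names,
    )


def annotate_junctions(
    junctions: Iterable[Junction],
    index: TranscriptomeIndex,
    genome: Optional[GenomeSequence] = None,
) -> pd.DataFrame:
    """Annotate junctions into a TSV-shaped table (one row per junction).

    The start/end columns are the intron coordinates (0-based, half-open);
    the anchor column is the junction type.
    """
    rows = []
    for junction in sorted(
        junctions, key=lambda j: (j.contig, j.intron_start, j.intron_end, j.strand)
    ):
        ann = classify_junction(junction, index, genome)
        rows.append(annotation_row(ann))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def annotation_row(ann: AnnotatedJunction) -> dict:
    j = ann.junction
    return {
        "chrom": j.contig,
        "start": j.intron_start,
        "end": j.intron_end,
        "name": j.name,
        "score": j.score,
        "strand": ann.strand,
        "splice_site": ann.splice_site,
        "acceptors_skipped": ann.acceptors_skipped,
        "donors_skipped": ann.donors_skipped,
        "exons_skipped": ann.exons_skipped,
        "anchor": ann.junction_type,
        "known_donor": int(ann.known_donor),
        "known_acceptor": int(ann.known_acceptor),
        "known_junction": int(ann.known_junction),
        "genes": ",".join(ann.genes),
        "transcripts": ",".join(ann.transcripts),
    }


def write_annotation_tsv(table: pd.DataFrame, out: TextIO) -> None:
    table.to_csv(out, sep="\t", index=False)
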