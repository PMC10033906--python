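"""Reference transcriptome and genome models.

All internal coordinates are 0-based, half-open.  GTF (1-based, inclusive)
and VCF (1-based) coordinates are converted at the I/O boundary; BED output
is native in the internal convention.

A :class:`TranscriptomeIndex` holds interval-indexed transcript models plus
the derived catalogs used by junction classification: the set of annotated
donor sites, acceptor sites, and donor-acceptor intron pairs.  Donor and
acceptor are defined with respect to the transcribed strand: for a ``+``
strand transcript the donor of intron *k* is the end coordinate of exon *k*
and the acceptor is the start coordinate of exon *k+1*; mirrored on ``-``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from intervaltree import IntervalTree

STRANDS = ("+", "-", "?")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open intersection test (abutting intervals do not overlap)."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered, non-overlapping exon chain on one strand."""

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        contig = self.exons[0].contig
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.contig != contig:
                raise ValueError("all exons must share one contig")
            if cur.start < prev.end:
                raise ValueError("exons must be sorted and non-overlapping")

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1

    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        )


class TranscriptomeIndex:
    """Interval-indexed transcript collection with splice-site catalogs."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.donors: set[tuple[str, int, str]] = set()
        self.acceptors: set[tuple[str, int, str]] = set()
        self.known_introns: set[tuple[str, int, int, str]] = set()
        self.genes: dict[str, list[str]] = {}
        self.gene_names: dict[str, str] = {}
        self._trees: dict[str, IntervalTree] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {tx.transcript_id!r}")
            self.transcripts[tx.transcript_id] = tx
            self.genes.setdefault(tx.gene_id, []).append(tx.transcript_id)
            self.gene_names.setdefault(tx.gene_id, tx.gene_name)
            span = tx.span
            self._trees.setdefault(tx.contig, IntervalTree()).addi(
                span.start, span.end, tx.transcript_id
            )
            for intron in tx.introns():
                if tx.strand == "+":
                    donor, acceptor = intron.start, intron.end
                else:
                    donor, acceptor = intron.end, intron.start
                self.donors.add((tx.contig, donor, tx.strand))
                self.acceptors.add((tx.contig, acceptor, tx.strand))
                self.known_introns.add(
                    (tx.contig, intron.start, intron.end, tx.strand)
                )
        for ids in self.genes.values():
            ids.sort()

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping_transcripts(
        self, interval: GenomicInterval
    ) -> list[TranscriptModel]:
        """Transcripts whose span intersects ``interval``, by transcript_id.

        Unknown contigs yield an empty list.
        """
        tree = self._trees.get(interval.contig)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(interval.start, interval.end))
        return [self.transcripts[tid] for tid in hits]

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.genes.get(gene_id, [])]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def parse_gtf(
    source: str | Path | Iterable[str], include_single_exon: bool = False
) -> TranscriptomeIndex:
    """Build a :class:`TranscriptomeIndex` from GTF exon records.

    Transcripts are assembled from ``exon`` feature lines only; ``transcript``
    feature lines are optional.  Duplicate exon lines are deduplicated
    silently.  Single-exon transcripts are excluded unless
    ``include_single_exon`` is set.  ``gene_name`` falls back to ``gene_id``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_gtf(fh, include_single_exon=include_single_exon)

    exons: dict[str, set[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (contig, strand, gene_id, gene_name)
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"malformed GTF line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        contig, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"malformed GTF line {lineno}: {exc}") from None
        if start1 < 1 or end1 < start1:
            raise GtfParseError(
                f"malformed GTF line {lineno}: bad coordinates {start_s}-{end_s}"
            )
        attributes = _parse_attributes(attrs)
        tid = attributes.get("transcript_id")
        if not tid:
            warnings.warn(
                f"GTF line {lineno}: exon without transcript_id rejected",
                stacklevel=2,
            )
            continue
        gene_id = attributes.get("gene_id", tid)
        gene_name = attributes.get("gene_name", gene_id)
        prev = meta.get(tid)
        if prev is not None and (prev[0], prev[1]) != (contig, strand):
            raise GtfParseError(
                f"malformed GTF line {lineno}: transcript {tid!r} changes "
                "contig or strand"
            )
        meta[tid] = (contig, strand, gene_id, gene_name)
        exons.setdefault(tid, set()).add((start1 - 1, end1))

    models = []
    for tid, coords in exons.items():
        contig, strand, gene_id, gene_name = meta[tid]
        if len(coords) == 1 and not include_single_exon:
            continue
        intervals = tuple(
            GenomicInterval(contig, s, e, strand) for s, e in sorted(coords)
        )
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                gene_name=gene_name,
                strand=strand,
                exons=intervals,
            )
        )
    models.sort(key=lambda t: t.transcript_id)
    return TranscriptomeIndex(models)


def write_gtf(index: TranscriptomeIndex | Iterable[TranscriptModel], out: TextIO) -> None:
    """Write transcripts back to GTF (exon lines only, 1-based inclusive)."""
    if isinstance(index, TranscriptomeIndex):
        transcripts: Iterable[TranscriptModel] = index.transcripts.values()
    else:
        transcripts = index
    for tx in sorted(transcripts, key=lambda t: (t.contig, t.span.start, t.transcript_id)):
        for exon in tx.exons:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_name}";'
            )
            out.write(
                "\t".join(
                    [
                        tx.contig,
                        "cissplice",
                        "exon",
                        str(exon.start + 1),
                        str(exon.end),
                        ".",
                        tx.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Contig-addressable nucleotide sequence with random access."""

    def __init__(self, fetcher, contigs: Iterable[str]):
        self._fetch = fetcher
        self.contigs = set(contigs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), sequence_always_upper=True)

        def fetch(contig: str, start: int, end: int) -> str:
            return str(fa[contig][start:end])

        return cls(fetch, fa.keys())

    @classmethod
    def from_dict(cls, sequences: dict[str, str]) -> "GenomeSequence":
        upper = {k: v.upper() for k, v in sequences.items()}

        def fetch(contig: str, start: int, end: int) -> str:
            return upper[contig][start:end]

        return cls(fetch, upper.keys())

    def fetch(self, contig: str, start: int, end: int) -> str:
        if contig not in self.contigs:
            raise KeyError(f"contig {contig!r} not in genome")
        if start < 0 or start >= end:
            raise ValueError(f"bad interval [{start}, {end})")
        seq = self._fetch(contig, start, end)
        if len(seq) != end - start:
            raise ValueError(
                f"interval [{start}, {end}) on {contig} extends past contig end"
            )
        return seq

    def fetch_interval(self, interval: GenomicInterval) -> str:
        return self.fetch(interval.contig, interval.start, interval.end)
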