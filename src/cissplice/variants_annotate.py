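"""Splice-relevance annotation of variants against a transcriptome.

Each variant is classified per overlapping transcript under a configurable
"splice variant window": intronic positions within ``intronic_bases`` of an
exon edge are ``splicing_intronic``, exonic positions within
``exonic_bases`` of an exon edge are ``splicing_exonic``; everything else is
plain ``intronic`` / ``exonic``.  The ``-I`` / ``-E`` style flags instead
treat every intronic / exonic position as potentially splice-relevant,
without changing the label.

Distance convention: the exonic or intronic base immediately adjacent to an
exon edge has distance 1, so a window of N bases captures exactly the N
nearest bases (``-i 2`` captures precisely the canonical splice
dinucleotide).  The reported distance is the minimum over the two edges of
the associated exon (for exonic positions) or the two flanking exon edges
(for intronic positions).

Indels are anchored at their leftmost reference-affected base; inputs are
required to be left-aligned, trimmed, and decomposed, which makes this
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .reference_model import GenomicInterval, TranscriptModel, TranscriptomeIndex

VARIANT_TYPES = (
    "splicing_exonic",
    "splicing_intronic",
    "exonic",
    "intronic",
    "not_relevant",
)

_INFO_FIELDS = ("genes", "transcripts", "distances", "variant_types")


@dataclass(frozen=True)
class SpliceVariantWindow:
    """Window configuration (-i/-e/-I/-E/-S)."""

    intronic_bases: int = 2
    exonic_bases: int = 3
    all_intronic: bool = False
    all_exonic: bool = False
    include_single_exon: bool = False

    def __post_init__(self) -> None:
        if self.intronic_bases < 0 or self.exonic_bases < 0:
            raise ValueError("window sizes must be >= 0")

    @classmethod
    def from_options(
        cls,
        intronic_bases: Optional[int] = None,
        exonic_bases: Optional[int] = None,
        all_intronic: bool = False,
        all_exonic: bool = False,
        include_single_exon: bool = False,
    ) -> "SpliceVariantWindow":
        if all_intronic and intronic_bases is not None:
            raise ValueError("-I excludes a finite intronic window (-i)")
        if all_exonic and exonic_bases is not None:
            raise ValueError("-E excludes a finite exonic window (-e)")
        return cls(
            intronic_bases=2 if intronic_bases is None else intronic_bases,
            exonic_bases=3 if exonic_bases is None else exonic_bases,
            all_intronic=all_intronic,
            all_exonic=all_exonic,
            include_single_exon=include_single_exon,
        )


@dataclass(frozen=True)
class VariantTranscriptAnnotation:
    transcript_id: str
    gene_id: str
    gene_name: str
    variant_type: str
    distance: int
    associated_exon: int

    def is_splice_relevant(self, window: SpliceVariantWindow) -> bool:
        """Whether this annotation feeds downstream splice analyses."""
        if self.variant_type in ("splicing_exonic", "splicing_intronic"):
            return True
        if self.variant_type == "exonic" and window.all_exonic:
            return True
        if self.variant_type == "intronic" and window.all_intronic:
            return True
        return False


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant (VCF 1-based) plus per-transcript splice annotations."""

    contig: str
    position: int  # 1-based, as in VCF
    ref: str
    alt: str
    annotations: tuple[VariantTranscriptAnnotation, ...] = ()

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def anchor_pos0(self) -> int:
        """Leftmost reference-affected base, 0-based."""
        pos0 = self.position - 1
        if (len(self.ref) > 1 or len(self.alt) > 1) and self.ref[0] == self.alt[0]:
            return pos0 + 1
        return pos0


def classify_variant(
    position0: int, transcript: TranscriptModel, window: SpliceVariantWindow
) -> VariantTranscriptAnnotation:
    """Classify a 0-based position within one transcript's span.

    Classification is exhaustive and mutually exclusive over positions in the
    span.  Terminal exon edges that abut no intron still anchor an exonic
    window (permissive reading of "exon edge").
    """
    span = transcript.span
    if not span.contains_point(position0):
        raise ValueError(
            f"position {position0} outside transcript span "
            f"[{span.start}, {span.end}) of {transcript.transcript_id}"
        )
    for k, exon in enumerate(transcript.exons):
        if exon.contains_point(position0):
            distance = min(position0 - exon.start + 1, exon.end - position0)
            if window.all_exonic:
                vtype = "exonic"
            elif distance <= window.exonic_bases:
                vtype = "splicing_exonic"
            else:
                vtype = "exonic"
            return VariantTranscriptAnnotation(
                transcript.transcript_id,
                transcript.gene_id,
                transcript.gene_name,
                vtype,
                distance,
                k,
            )
    for k, (left, right) in enumerate(zip(transcript.exons, transcript.exons[1:])):
        if left.end <= position0 < right.start:
            d_up = position0 - left.end + 1
            d_down = right.start - position0
            distance = min(d_up, d_down)
            associated = k if d_up <= d_down else k + 1
            if window.all_intronic:
                vtype = "intronic"
            elif distance <= window.intronic_bases:
                vtype = "splicing_intronic"
            else:
                vtype = "intronic"
            return VariantTranscriptAnnotation(
                transcript.transcript_id,
                transcript.gene_id,
                transcript.gene_name,
                vtype,
                distance,
                associated,
            )
    raise AssertionError("unreachable: span position neither exonic nor intronic")


_VALID_ALLELE = frozenset("ACGTN")


def _is_simple_allele(allele: str) -> bool:
    return bool(allele) and set(allele.upper()) <= _VALID_ALLELE


def annotate_variant_tuple(
    contig: str,
    position: int,
    ref: str,
    alt: str,
    index: TranscriptomeIndex,
    window: SpliceVariantWindow,
) -> AnnotatedVariant:
    """Annotate a single (contig, 1-based pos, ref, alt) variant."""
    variant = AnnotatedVariant(contig, position, ref, alt)
    pos0 = variant.anchor_pos0
    annotations = []
    for tx in index.overlapping_transcripts(
        GenomicInterval(contig, pos0, pos0 + 1)
    ):
        if tx.span.contains_point(pos0):
            annotations.append(classify_variant(pos0, tx, window))
    return AnnotatedVariant(contig, position, ref, alt, tuple(annotations))


def annotate_variants(
    vcf_path: str,
    index: TranscriptomeIndex,
    window: SpliceVariantWindow,
    out_path: Optional[str] = None,
) -> list[AnnotatedVariant]:
    """Annotate every record of a sorted VCF; optionally write annotated VCF.

    The INFO column of annotated records gains four parallel comma-separated
    lists (genes, transcripts, distances, variant_types), one entry per
    overlapping transcript.  Records with no overlap pass through unchanged.
    Multi-allelic records are rejected; inputs must be decomposed upstream.
    """
    import pysam

    results: list[AnnotatedVariant] = []
    vcf = pysam.VariantFile(vcf_path)
    header = vcf.header.copy()
    for name, desc in zip(
        _INFO_FIELDS,
        (
            "Variant-overlapping gene names",
            "Variant-overlapping transcripts",
            "Min distance to the associated exon edge, per transcript",
            "Splice-relevance class per transcript",
        ),
    ):
        if name not in header.info:
            header.info.add(name, ".", "String", desc)
    writer = pysam.VariantFile(out_path, "w", header=header) if out_path else None
    try:
        last: dict[str, int] = {}
        for record in vcf:
            if record.alts is None or len(record.alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {record.chrom}:{record.pos}; "
                    "decompose (left-align, trim, split) the VCF first"
                )
            if record.chrom in last and record.pos < last[record.chrom]:
                raise ValueError(
                    f"VCF not coordinate-sorted at {record.chrom}:{record.pos}"
                )
            last[record.chrom] = record.pos
            alt = record.alts[0]
            if not (_is_simple_allele(record.ref) and _is_simple_allele(alt)):
                warnings.warn(
                    f"symbolic or structural allele at {record.chrom}:{record.pos} "
                    "skipped",
                    stacklevel=2,
                )
                if writer is not None:
                    writer.write(record)
                continue
            annotated = annotate_variant_tuple(
                record.chrom, record.pos, record.ref, alt, index, window
            )
            results.append(annotated)
            if writer is not None:
                out_rec = record.copy()
                out_rec.translate(header)
                if annotated.annotations:
                    anns = annotated.annotations
                    out_rec.info["genes"] = ",".join(a.gene_name for a in anns)
                    out_rec.info["transcripts"] = ",".join(
                        a.transcript_id for a in anns
                    )
                    out_rec.info["distances"] = ",".join(
                        str(a.distance) for a in anns
                    )
                    out_rec.info["variant_types"] = ",".join(
                        a.variant_type for a in anns
                    )
                writer.write(out_rec)
    finally:
        vcf.close()
        if writer is not None:
            writer.close()
    return results


def read_vcf_variants(vcf_path: str) -> list[tuple[str, int, str, str]]:
    """Read (contig, 1-based pos, ref, alt) tuples from a VCF."""
    import pysam

    out = []
    with pysam.VariantFile(vcf_path) as vcf:
        for record in vcf:
            for alt in record.alts or ():
                out.append((record.chrom, record.pos, record.ref, alt))
    return out
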