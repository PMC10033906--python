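"""Pipeline: splice-junction regions per variant, and variant-junction events.

For each splice-relevant variant annotation a "splice junction region" is
computed: the largest span between the exons flanking the variant-associated
exon (clamped to the transcript span at terminal exons), or the containing
intron for plain intronic variants, or a fixed window centered on the
variant when a size override is given.  When several transcripts yield
regions, the union span (largest extent) is used.  A junction is associated
with a variant when its intron span intersects the variant's region
(half-open semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .junctions_annotate import (
    ANNOTATION_COLUMNS,
    AnnotatedJunction,
    annotation_row,
    classify_junction,
)
from .junctions_extract import (
    DEFAULT_MAX_INTRON,
    DEFAULT_MIN_ANCHOR,
    DEFAULT_MIN_INTRON,
    Junction,
    extract_junctions,
    read_bed12,
    write_bed12,
)
from .reference_model import GenomeSequence, GenomicInterval, TranscriptomeIndex, TranscriptModel
from .variants_annotate import (
    AnnotatedVariant,
    SpliceVariantWindow,
    VariantTranscriptAnnotation,
    annotate_variants,
)

EVENT_COLUMNS = [
    "variant_contig",
    "variant_pos",
    "variant_ref",
    "variant_alt",
    "variant_genes",
    "region_start",
    "region_end",
] + ANNOTATION_COLUMNS + ["associated_variants"]


@dataclass(frozen=True)
class SpliceJunctionRegion:
    variant: AnnotatedVariant
    interval: GenomicInterval


@dataclass(frozen=True)
class Event:
    """A (variant, associated junction) pair."""

    variant: AnnotatedVariant
    region: GenomicInterval
    junction: AnnotatedJunction


@dataclass(frozen=True)
class IdentifyParams:
    window: SpliceVariantWindow = SpliceVariantWindow()
    w_override: Optional[int] = None
    min_anchor: int = DEFAULT_MIN_ANCHOR
    min_intron: int = DEFAULT_MIN_INTRON
    max_intron: int = DEFAULT_MAX_INTRON
    strandness: int = 0


def splice_junction_region(
    annotation: VariantTranscriptAnnotation,
    transcript: TranscriptModel,
    variant_pos0: int,
    w_override: Optional[int] = None,
) -> GenomicInterval:
    """Region for one splice-relevant annotation on one transcript."""
    if annotation.variant_type == "not_relevant":
        raise ValueError("region undefined for a not_relevant annotation")
    contig = transcript.contig
    if w_override is not None:
        if w_override < 2:
            raise ValueError("window override must be >= 2 bases")
        start = max(0, variant_pos0 - w_override // 2)
        return GenomicInterval(contig, start, start + w_override)
    if annotation.variant_type == "intronic":
        # the containing intron
        for intron in transcript.introns():
            if intron.contains_point(variant_pos0):
                return GenomicInterval(contig, intron.start, intron.end)
        raise ValueError("intronic annotation but no containing intron found")
    exons = transcript.exons
    k = annotation.associated_exon
    start = exons[k - 1].end if k > 0 else transcript.span.start
    end = exons[k + 1].start if k < len(exons) - 1 else transcript.span.end
    return GenomicInterval(contig, start, end)


def variant_region(
    variant: AnnotatedVariant,
    index: TranscriptomeIndex,
    window: SpliceVariantWindow,
    w_override: Optional[int] = None,
) -> Optional[GenomicInterval]:
    """Union span of per-transcript regions over splice-relevant annotations.

    Returns None when no annotation is splice-relevant under the window.
    """
    intervals = []
    for ann in variant.annotations:
        if not ann.is_splice_relevant(window):
            continue
        tx = index.transcripts[ann.transcript_id]
        intervals.append(
            splice_junction_region(ann, tx, variant.anchor_pos0, w_override)
        )
    if not intervals:
        return None
    return GenomicInterval(
        intervals[0].contig,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


def associate(
    regions: Iterable[SpliceJunctionRegion],
    junctions: Iterable[AnnotatedJunction],
) -> list[Event]:
    """Emit one event per (variant, junction) pair with overlapping spans."""
    junctions = list(junctions)
    events = []
    for region in regions:
        for ann in junctions:
            if region.interval.overlaps(ann.interval):
                events.append(Event(region.variant, region.interval, ann))
    events.sort(
        key=lambda e: (
            e.variant.contig,
            e.variant.position,
            e.variant.ref,
            e.variant.alt,
            e.junction.junction.key,
        )
    )
    return events


def events_table(events: Iterable[Event]) -> pd.DataFrame:
    """Event TSV: one row per pair; each junction row also carries the full
    list of variants associated with that junction."""
    events = list(events)
    per_junction: dict[tuple, list[str]] = {}
    for e in events:
        key = e.junction.junction.key
        label = f"{e.variant.contig}:{e.variant.position}:{e.variant.ref}>{e.variant.alt}"
        per_junction.setdefault(key, []).append(label)
    for labels in per_junction.values():
        labels.sort()
    rows = []
    for e in events:
        relevant_genes = sorted(
            {
                a.gene_name
                for a in e.variant.annotations
                if a.variant_type.startswith("splicing")
                or a.variant_type in ("exonic", "intronic")
            }
        )
        row = {
            "variant_contig": e.variant.contig,
            "variant_pos": e.variant.position,
            "variant_ref": e.variant.ref,
            "variant_alt": e.variant.alt,
            "variant_genes": ",".join(relevant_genes),
            "region_start": e.region.start,
            "region_end": e.region.end,
        }
        row.update(annotation_row(e.junction))
        row["associated_variants"] = ",".join(
            per_junction[e.junction.junction.key]
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _annotated_regions(
    annotated_variants: Iterable[AnnotatedVariant],
    index: TranscriptomeIndex,
    params: IdentifyParams,
) -> list[SpliceJunctionRegion]:
    regions = []
    for variant in annotated_variants:
        interval = variant_region(variant, index, params.window, params.w_override)
        if interval is not None:
            regions.append(SpliceJunctionRegion(variant, interval))
    return regions


def _associate_junctions(
    regions: list[SpliceJunctionRegion],
    junctions: list[Junction],
    index: TranscriptomeIndex,
    genome: Optional[GenomeSequence],
) -> tuple[list[Junction], list[Event]]:
    regional = [
        j
        for j in junctions
        if any(r.interval.overlaps(j.interval) for r in regions)
    ]
    annotated = [classify_junction(j, index, genome) for j in regional]
    return regional, associate(regions, annotated)


def identify(
    vcf_path: str,
    alignment_path: str,
    index: TranscriptomeIndex,
    genome: Optional[GenomeSequence],
    params: IdentifyParams = IdentifyParams(),
    variant_out: Optional[str] = None,
    junctions_out: Optional[str] = None,
) -> pd.DataFrame:
    """Full pipeline: annotate variants, extract junctions, associate."""
    annotated = annotate_variants(vcf_path, index, params.window, out_path=variant_out)
    regions = _annotated_regions(annotated, index, params)
    junctions = extract_junctions(
        alignment_path,
        strandness=params.strandness,
        min_anchor=params.min_anchor,
        min_intron=params.min_intron,
        max_intron=params.max_intron,
    )
    regional, events = _associate_junctions(regions, junctions, index, genome)
    if junctions_out is not None:
        with open(junctions_out, "w") as fh:
            write_bed12(regional, fh)
    return events_table(events)


def associate_mode(
    vcf_path: str,
    junction_bed: str,
    index: TranscriptomeIndex,
    genome: Optional[GenomeSequence],
    params: IdentifyParams = IdentifyParams(),
    variant_out: Optional[str] = None,
) -> pd.DataFrame:
    """As :func:`identify`, with junctions loaded from BED12, not extracted."""
    annotated = annotate_variants(vcf_path, index, params.window, out_path=variant_out)
    regions = _annotated_regions(annotated, index, params)
    junctions = read_bed12(junction_bed)
    _, events = _associate_junctions(regions, junctions, index, genome)
    return events_table(events)
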