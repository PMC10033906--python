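"""Cohort-level statistics for variant-junction events.

For one sample, a junction's ``norm_score`` is its read count divided by the
summed read count of all junctions overlapping the variant's splice junction
region (a PSI-like usage fraction over whole junctions; 0 when the region
has no reads).  The ``mean_norm_score`` of an event is the mean over
variant-containing samples, and the empirical p-value is the fraction of
non-variant samples whose norm_score is at least as high (ties count
toward the p-value).  Samples without reads in the region contribute
norm_score 0 to the null distribution.

Separate analyses are run for events on known junctions (DA) and on
non-reference junctions that use at least one known splice site (D/A/NDA);
junctions using no known site (N) are excluded, as are events with fewer
than 5 reads of junction evidence across variant-containing samples.
Benjamini-Hochberg correction is applied within each analysis and events
with adjusted p <= 0.05 are flagged significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cis_splice_effects import variant_region
from .junctions_annotate import classify_junction
from .junctions_extract import Junction, extract_junctions, read_bed12
from .reference_model import GenomicInterval, TranscriptomeIndex
from .variants_annotate import (
    SpliceVariantWindow,
    annotate_variant_tuple,
    read_vcf_variants,
)

NON_REFERENCE_CLASSES = frozenset({"D", "A", "NDA"})
REFERENCE_CLASSES = frozenset({"DA"})
DEFAULT_MIN_READS = 5
DEFAULT_ALPHA = 0.05

EVENT_STAT_COLUMNS = [
    "variant_contig",
    "variant_pos",
    "variant_ref",
    "variant_alt",
    "variant_genes",
    "junction_contig",
    "junction_start",
    "junction_end",
    "junction_strand",
    "junction_type",
    "region_start",
    "region_end",
    "n_variant_samples",
    "variant_samples",
    "n_non_variant_samples",
    "total_variant_reads",
    "mean_norm_score",
    "mean_non_variant_norm_score",
    "p_value",
    "adjusted_p",
    "significant",
]


@dataclass
class CohortSample:
    """One cohort member: a junction source and a variant source.

    Single-cell analyses reuse this machinery by treating each cell as an
    individual sample.
    """

    sample_id: str
    junctions: list[Junction]
    variants: set[tuple[str, int, str, str]]

    @classmethod
    def load(
        cls, sample_id: str, junction_path: str, vcf_path: str, strandness: int = 0
    ) -> "CohortSample":
        path = str(junction_path)
        if path.endswith((".bed", ".bed12")):
            junctions = read_bed12(path)
        else:
            junctions = extract_junctions(path, strandness=strandness)
        return cls(
            sample_id=sample_id,
            junctions=junctions,
            variants=set(read_vcf_variants(vcf_path)),
        )


def load_cohort_manifest(path: str | Path, strandness: int = 0) -> list[CohortSample]:
    """Read a manifest TSV (sample_id, junction path, VCF path)."""
    samples = []
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample_id, junc, vcf = line.split("\t")[:3]
            junc_p = junc if Path(junc).is_absolute() else str(base / junc)
            vcf_p = vcf if Path(vcf).is_absolute() else str(base / vcf)
            samples.append(CohortSample.load(sample_id, junc_p, vcf_p, strandness))
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique within a cohort")
    return samples


def norm_score(
    junction_key: tuple[str, int, int, str],
    region: GenomicInterval,
    sample_junctions: Sequence[Junction],
) -> float:
    """reads(junction) / total reads over junctions overlapping the region."""
    total = 0
    count = 0
    for j in sample_junctions:
        if j.interval.overlaps(region):
            total += j.score
            if j.key == junction_key:
                count += j.score
    return count / total if total else 0.0


def empirical_p_value(
    mean_norm: float, non_variant_scores: Sequence[float]
) -> float:
    """Fraction of non-variant norm_scores at least as high as the mean."""
    m = len(non_variant_scores)
    if m == 0:
        return math.nan
    return sum(1 for s in non_variant_scores if s >= mean_norm) / m


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment, order-preserving with the input."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sample_region_index(sample: CohortSample) -> IntervalTree | dict:
    trees: dict[str, IntervalTree] = {}
    for j in sample.junctions:
        trees.setdefault(j.contig, IntervalTree()).addi(
            j.intron_start, j.intron_end, j
        )
    return trees


def compare_junctions(
    samples: Sequence[CohortSample],
    index: TranscriptomeIndex,
    window: SpliceVariantWindow = SpliceVariantWindow(),
    junction_classes: frozenset = NON_REFERENCE_CLASSES,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    w_override: Optional[int] = None,
    chunk_size: Optional[int] = None,
) -> pd.DataFrame:
    """Score every (variant, junction) event across a cohort.

    Events are built per splice-relevant variant from the union of junctions
    observed in variant-containing samples within the variant's region, then
    filtered by junction class and total variant-sample read support, scored
    with the empirical statistic, and BH-corrected within this analysis.
    ``chunk_size`` bounds how many variants are held in flight at once and
    must not change any statistic.
    """
    if junction_classes not in (NON_REFERENCE_CLASSES, REFERENCE_CLASSES):
        raise ValueError(
            "junction_classes must be the DA set or the D/A/NDA set"
        )
    if not samples:
        raise ValueError("empty cohort")
    sample_trees = [_sample_region_index(s) for s in samples]
    sample_keys = [
        {j.key: j.score for j in s.junctions} for s in samples
    ]

    all_variants = sorted({v for s in samples for v in s.variants})
    rows: list[dict] = []
    chunk = len(all_variants) if not chunk_size else chunk_size
    for start in range(0, len(all_variants), max(chunk, 1)):
        for variant in all_variants[start : start + chunk]:
            rows.extend(
                _variant_events(
                    variant,
                    samples,
                    sample_trees,
                    sample_keys,
                    index,
                    window,
                    junction_classes,
                    min_reads,
                    w_override,
                )
            )
    table = pd.DataFrame(rows, columns=EVENT_STAT_COLUMNS)
    if len(table):
        testable = table["p_value"].notna()
        adjusted = np.full(len(table), np.nan)
        if testable.any():
            adjusted[testable.to_numpy()] = benjamini_hochberg(
                table.loc[testable, "p_value"].to_numpy()
            )
        table["adjusted_p"] = adjusted
        table["significant"] = (table["adjusted_p"] <= alpha).fillna(False)
    return table


def _variant_events(
    variant: tuple[str, int, str, str],
    samples: Sequence[CohortSample],
    sample_trees: Sequence[dict],
    sample_keys: Sequence[dict],
    index: TranscriptomeIndex,
    window: SpliceVariantWindow,
    junction_classes: frozenset,
    min_reads: int,
    w_override: Optional[int],
) -> list[dict]:
    contig, pos, ref, alt = variant
    annotated = annotate_variant_tuple(contig, pos, ref, alt, index, window)
    region = variant_region(annotated, index, window, w_override)
    if region is None:
        return []
    variant_idx = [i for i, s in enumerate(samples) if variant in s.variants]
    non_variant_idx = [i for i, s in enumerate(samples) if variant not in s.variants]
    if not variant_idx:
        return []
    # candidate junctions: union over variant-containing samples in the region
    candidates: dict[tuple, Junction] = {}
    for i in variant_idx:
        tree = sample_trees[i].get(contig)
        if tree is None:
            continue
        for iv in tree.overlap(region.start, region.end):
            candidates.setdefault(iv.data.key, iv.data)

    # per-sample region denominators
    denominators = []
    for i, sample in enumerate(samples):
        tree = sample_trees[i].get(contig)
        total = 0
        if tree is not None:
            total = sum(iv.data.score for iv in tree.overlap(region.start, region.end))
        denominators.append(total)

    genes = sorted(
        {
            a.gene_name
            for a in annotated.annotations
            if a.is_splice_relevant(window)
        }
    )
    rows = []
    for key in sorted(candidates):
        junction = candidates[key]
        ann = classify_junction(junction, index)
        if ann.junction_type not in junction_classes:
            continue
        total_variant_reads = sum(sample_keys[i].get(key, 0) for i in variant_idx)
        if total_variant_reads < min_reads:
            continue
        scores = [
            (sample_keys[i].get(key, 0) / denominators[i]) if denominators[i] else 0.0
            for i in range(len(samples))
        ]
        variant_scores = [scores[i] for i in variant_idx]
        non_variant_scores = [scores[i] for i in non_variant_idx]
        mean_norm = float(np.mean(variant_scores))
        p = empirical_p_value(mean_norm, non_variant_scores)
        rows.append(
            {
                "variant_contig": contig,
                "variant_pos": pos,
                "variant_ref": ref,
                "variant_alt": alt,
                "variant_genes": ",".join(genes),
                "junction_contig": key[0],
                "junction_start": key[1],
                "junction_end": key[2],
                "junction_strand": key[3],
                "junction_type": ann.junction_type,
                "region_start": region.start,
                "region_end": region.end,
                "n_variant_samples": len(variant_idx),
                "variant_samples": ",".join(
                    samples[i].sample_id for i in variant_idx
                ),
                "n_non_variant_samples": len(non_variant_idx),
                "total_variant_reads": total_variant_reads,
                "mean_norm_score": mean_norm,
                "mean_non_variant_norm_score": (
                    float(np.mean(non_variant_scores))
                    if non_variant_scores
                    else math.nan
                ),
                "p_value": p,
                "adjusted_p": math.nan,
                "significant": False,
            }
        )
    return rows
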