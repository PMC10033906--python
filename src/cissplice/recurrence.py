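"""Gene-level recurrence of splice-associated variants.

Per gene, the chance that a sample acquires at least one splice-associated
variant by chance is modeled as

    p_null = 1 - (1 - Pr(V and A))**s

where ``s`` is the number of distinct genomic positions inside any of the
gene's splice-variant windows (its footprint) and ``Pr(V and A)`` is the
joint probability that a footprint position carries a somatic variant and
that variant is significantly associated with at least one junction,
estimated cohort-wide as (significant splice-associated variants summed
over samples) / (footprint summed over all genes).  A one-tailed binomial
test with the cohort size as the number of attempts and "sample has at
least one significant splice-associated variant in the gene" as success
yields the recurrence p-value; the fraction of samples is reported
alongside as a second ranking metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .reference_model import TranscriptModel, TranscriptomeIndex
from .variants_annotate import SpliceVariantWindow

GENE_TABLE_COLUMNS = [
    "gene",
    "gene_name",
    "cohort",
    "n_samples",
    "k_samples",
    "footprint",
    "pr_va",
    "p_null",
    "binom_p",
    "fraction",
]


@dataclass(frozen=True)
class RecurrenceModel:
    s: int
    pr_va: float
    p_null: float
    n_samples: int
    k_success: int


def gene_footprint(
    transcripts: Sequence[TranscriptModel], window: SpliceVariantWindow
) -> int:
    """Distinct genomic positions in any of the gene's splice-variant windows.

    Each intron contributes ``exonic_bases`` into each flanking exon and
    ``intronic_bases`` into the intron on each side; under the all-exonic /
    all-intronic flags every exonic / intronic gene position counts.
    Positions are deduplicated across transcripts and edges.
    """
    positions: set[int] = set()
    for tx in transcripts:
        if window.all_exonic:
            for exon in tx.exons:
                positions.update(range(exon.start, exon.end))
        if window.all_intronic:
            for intron in tx.introns():
                positions.update(range(intron.start, intron.end))
        for intron in tx.introns():
            if not window.all_intronic:
                i = window.intronic_bases
                positions.update(
                    range(intron.start, min(intron.start + i, intron.end))
                )
                positions.update(
                    range(max(intron.end - i, intron.start), intron.end)
                )
            if not window.all_exonic:
                e = window.exonic_bases
                # upstream-in-genome exon ends at intron.start
                for exon in tx.exons:
                    if exon.end == intron.start:
                        positions.update(
                            range(max(exon.end - e, exon.start), exon.end)
                        )
                    if exon.start == intron.end:
                        positions.update(
                            range(exon.start, min(exon.start + e, exon.end))
                        )
    return len(positions)


def total_footprint(index: TranscriptomeIndex, window: SpliceVariantWindow) -> int:
    """Footprint positions across all genes (union over genes per contig)."""
    total = 0
    for gene_id in index.genes:
        total += gene_footprint(index.gene_transcripts(gene_id), window)
    return total


def estimate_joint_probability(
    n_significant_variants: int, footprint: int
) -> float:
    """Pr(V and A) estimator: significant variants / total footprint."""
    if footprint <= 0:
        raise ValueError("total footprint must be > 0")
    ratio = n_significant_variants / footprint
    if ratio > 1:
        warnings.warn("joint probability estimate exceeds 1; clamped", stacklevel=2)
        return 1.0
    return ratio


def p_null(pr_va: float, s: int) -> float:
    """1 - (1 - pr_va)**s, stable for small pr_va and large s."""
    if not 0.0 <= pr_va <= 1.0:
        raise ValueError("pr_va must lie in [0, 1]")
    if s < 0:
        raise ValueError("s must be >= 0")
    if s == 0 or pr_va == 0.0:
        return 0.0
    if pr_va == 1.0:
        return 1.0
    return -math.expm1(s * math.log1p(-pr_va))


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def _significant_events(
    events: pd.DataFrame, junction_classes: Iterable[str]
) -> pd.DataFrame:
    classes = set(junction_classes)
    sig = events[events["significant"].astype(bool)]
    return sig[sig["junction_type"].isin(classes)]


def cohort_recurrence(
    events: pd.DataFrame,
    n_samples: int,
    index: TranscriptomeIndex,
    window: SpliceVariantWindow = SpliceVariantWindow(),
    junction_classes: Iterable[str] = ("D", "A", "NDA"),
    cohort: str = "cohort",
    total_footprint_value: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene recurrence table for one cohort.

    ``events`` is a compare_junctions table (significant events are selected
    here).  Every gene of the annotation is reported, ranked by binomial
    p-value; re-sort by ``fraction`` for the second metric.
    """
    if n_samples < 1:
        raise ValueError("cohort must have at least one sample")
    sig = _significant_events(events, junction_classes)

    # distinct (sample, variant) significant pairs, and per-gene sample sets
    sample_variant: set[tuple[str, tuple]] = set()
    gene_samples: dict[str, set[str]] = {}
    name_to_gene = {v: k for k, v in index.gene_names.items()}
    for _, row in sig.iterrows():
        vkey = (
            row["variant_contig"],
            row["variant_pos"],
            row["variant_ref"],
            row["variant_alt"],
        )
        samples = [s for s in str(row["variant_samples"]).split(",") if s]
        for s in samples:
            sample_variant.add((s, vkey))
        for gene_label in str(row["variant_genes"]).split(","):
            if not gene_label:
                continue
            gene_id = name_to_gene.get(gene_label, gene_label)
            gene_samples.setdefault(gene_id, set()).update(samples)

    if total_footprint_value is None:
        total_footprint_value = total_footprint(index, window)
    pr = estimate_joint_probability(len(sample_variant), total_footprint_value)

    rows = []
    for gene_id in sorted(index.genes):
        s_gene = gene_footprint(index.gene_transcripts(gene_id), window)
        k = len(gene_samples.get(gene_id, ()))
        null = p_null(pr, s_gene)
        rows.append(
            {
                "gene": gene_id,
                "gene_name": index.gene_names[gene_id],
                "cohort": cohort,
                "n_samples": n_samples,
                "k_samples": k,
                "footprint": s_gene,
                "pr_va": pr,
                "p_null": null,
                "binom_p": binomial_upper_tail(k, n_samples, null),
                "fraction": k / n_samples,
            }
        )
    table = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    return table.sort_values(
        ["binom_p", "gene"], kind="mergesort", ignore_index=True
    )


def pooled_recurrence(
    cohorts: Sequence[tuple[str, pd.DataFrame, int]],
    index: TranscriptomeIndex,
    window: SpliceVariantWindow = SpliceVariantWindow(),
    junction_classes: Iterable[str] = ("D", "A", "NDA"),
) -> pd.DataFrame:
    """Pool samples across cohorts and recompute both metrics.

    ``cohorts`` is a sequence of (name, events table, n_samples).  Sample
    identifiers are namespaced by cohort so identical ids in different
    cohorts stay distinct.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    frames = []
    total_n = 0
    for name, events, n in cohorts:
        events = events.copy()
        if len(events):
            events["variant_samples"] = events["variant_samples"].map(
                lambda s: ",".join(
                    f"{name}:{x}" for x in str(s).split(",") if x
                )
            )
        frames.append(events)
        total_n += n
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return cohort_recurrence(
        pooled,
        total_n,
        index,
        window=window,
        junction_classes=junction_classes,
        cohort="pooled",
    )


def rank_genes(table: pd.DataFrame, by: str = "binom_p") -> pd.DataFrame:
    """Rank genes by ``binom_p`` (ascending) or ``fraction`` (descending)."""
    if by == "binom_p":
        return table.sort_values(
            ["binom_p", "gene"], kind="mergesort", ignore_index=True
        )
    if by == "fraction":
        return table.sort_values(
            ["fraction", "gene"],
            ascending=[False, True],
            kind="mergesort",
            ignore_index=True,
        )
    raise ValueError("rank metric must be 'binom_p' or 'fraction'")
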