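# Methods

`cissplice` identifies *cis*-acting splice-associated variants: somatic
variants that sit close enough to an exon edge to plausibly disrupt splicing,
and that co-occur with shifted splice-junction usage in the samples that carry
them. This note documents the model, its parameters, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Coordinate and distance conventions

All internal coordinates are 0-based, half-open. GTF (1-based inclusive) and
VCF (1-based) are converted at the I/O boundary; BED output is native in the
internal convention. Overlap tests are half-open throughout: an interval
ending exactly where another begins does not overlap it.

Distances to exon edges start at 1 for the base immediately adjacent to the
edge, so a window of *N* bases captures exactly the *N* nearest bases —
`-i 2` captures precisely the canonical GT/AG splice dinucleotide. The
reported distance per transcript is min(distance to exon start, distance to
exon end) for the associated exon. Indels are anchored at their leftmost
reference-affected base; inputs are required to be left-aligned, trimmed and
decomposed, which makes the anchor deterministic.

## Variant classification

Per overlapping transcript, a position is `splicing_intronic` when within
`intronic_bases` (default 2) of a flanking exon edge, `splicing_exonic` when
within `exonic_bases` (default 3) of its exon's edges, otherwise plain
`intronic` / `exonic`. The all-intronic / all-exonic flags make every
intronic / exonic position splice-relevant without changing its label.
Classification is exhaustive and mutually exclusive over the transcript span.
A variant in the terminal window of a first/last exon edge that abuts no
intron is still labeled `splicing_exonic`; this is the permissive reading of
"exon edge" (see the footprint caveat below). Per-transcript annotations are
kept separate rather than collapsed to a most-severe call.

## Junction extraction

Each `N` CIGAR operator of a usable alignment (mapped, primary,
non-supplementary; duplicate/QC-fail excluded by default) yields one junction
observation. Anchors count reference-consuming operators (M/=/X/D) between
the read end or adjacent skip and the skip; insertions and clips contribute
nothing. Treating a deletion abutting an `N` as anchor-consuming is a dialect
choice forced by coordinate correctness of the reference walk. Observations
aggregate by (contig, intron start, intron end, strand) — strands are
distinct keys — and a junction is kept when its *maximal* anchor on each side
(union rule across reads) reaches `min_anchor` (default 8) and its length
lies in [`min_intron`, `max_intron`] (defaults 70 and 500,000). BED12 names
are derived from coordinates (`JUNC:contig:start-end:strand`) rather than a
serial number so that region-restricted extraction and whole-file extraction
produce identical rows — a serial scheme would renumber under restriction and
break the pipeline-equals-composition identity.

## Junction classification

Donor = 5' intron boundary with respect to the transcribed strand, acceptor =
3'. Matching against the annotated donor/acceptor/intron catalogs is exact to
the base. The five types partition all junctions: DA (annotated pair), NDA
(both sites known, pair novel), D / A (one site known), N (neither).
Unknown-strand junctions are evaluated on both strands and the higher class
wins (DA > NDA > D = A > N), ties to `+`; this makes unstranded libraries
usable. Skipped donors/acceptors are distinct annotated site positions
strictly inside the intron, skipped exons are annotated exons fully contained
in it, counted per overlapping gene with the per-gene maximum reported —
distinct-position counting avoids double-counting sites shared between
isoforms. Read-through junctions whose two sites belong to different genes
list both genes.

## Splice-junction regions and events

For a splice-relevant variant annotation the region spans from the 3' end of
the exon upstream of the variant-associated exon to the 5' end of the exon
downstream of it, clamped to the transcript span at terminal exons (the
upstream neighbor of exon 1 is undefined; clamping is the conservative
choice). For a `splicing_intronic` variant the associated exon is the one
whose window captured it (nearest edge). Plain `intronic` variants (under the
all-intronic flag) use the containing intron. A fixed-size override window is
interpreted as a total size centered on the variant. When several transcripts
yield regions, the union span is used, consistently for both the variant- and
non-variant-sample sides of the statistic. An event is any (variant,
junction) pair whose region and intron span intersect.

## The cohort statistic

Per sample, `norm_score(junction) = reads(junction) / Σ reads(junctions
overlapping the region)` — a PSI-like usage fraction over whole junctions; 0
when the region has no reads. `mean_norm_score` averages the
variant-containing samples, and the empirical p-value is the fraction of
non-variant samples with `norm_score ≥ mean_norm_score` (ties count; samples
with no reads in the region contribute 0 — excluding them would bias p
downward). Events are analysed separately for DA junctions and for D/A/NDA
junctions; N junctions and events with fewer than 5 reads of junction
evidence across variant-containing samples are excluded before
Benjamini–Hochberg correction (statsmodels step-up), and events with adjusted
p ≤ 0.05 are significant. BH is applied per cohort per junction-class
analysis. Variant-containing samples are determined by exact (contig, pos,
ref, alt) match in the sample's VCF. Processing is chunked by variant; since
events are independent and BH is applied after collection, chunking cannot
change any statistic (tested).

## Gene recurrence

For gene *g* with footprint *s* (distinct genomic positions inside any of the
gene's splice-variant windows), the per-sample null probability of acquiring
at least one splice-associated variant is

    p_null = 1 − (1 − Pr(V ∧ A))^s

with Pr(V ∧ A) estimated as (significant splice-associated variants summed
over cohort samples) / (total footprint over all genes), clamped to [0, 1].
The footprint counts, per intron, `exonic_bases` into each flanking exon and
`intronic_bases` into the intron on each side, deduplicated across
transcripts and edges; under the all-exonic / all-intronic flags, every
exonic / intronic gene position counts. Terminal exon edges that abut no
intron are *not* part of the footprint even though the classifier labels
variants there `splicing_exonic`; the two conventions are deliberately kept
as specified and the resulting numerator/denominator mismatch is negligible
except in degenerate two-exon annotations. A one-tailed binomial upper tail
P(X ≥ k | n, p_null) with the cohort size as attempts and "sample has ≥ 1
significant splice-associated variant in the gene" as success gives the
recurrence p-value; the fraction of samples k/n is the second ranking metric.
Pooling concatenates samples across cohorts (namespaced so identical sample
ids stay distinct) and recomputes both metrics. The default junction-class
set for recurrence is D/A/NDA; a flag selects DA. `p_null` is evaluated as
`-expm1(s * log1p(-p))`, accurate to ≥ 12 significant digits against
arbitrary-precision arithmetic over pr ∈ [1e-12, 1], s ∈ [0, 1e7].

Requiring *significance* in the success definition (not merely the presence
of a splice-window variant) is a deliberate reading: recurrence operates on
the significant-event tables, so an unfiltered definition would mix tested
and untested variants.

## Synthetic data generator

The generator emulates exactly the structures the method consumes: a random
genome carrying multi-exon genes (alternating strands) whose introns have
canonical GT-AG motifs on their own strand; per-sample VCFs in which a chosen
subset of samples carries a single-nucleotide variant at the second intronic
base of the first intron's acceptor (the A of the AG dinucleotide); and reads
or junction counts in which those samples reroute a configured fraction of
transcript molecules to a cryptic junction — an exon skip (NDA) or a cryptic
donor (A on `+` genes, D on `−` genes). Per gene and sample, `read_depth`
molecules are split binomially between canonical and cryptic isoforms at the
sample's rerouted fraction ψ (baseline alternative usage + effect in variant
samples), and each junction's read count is a Binomial(2·molecules, ½)
depth-noise draw, so at ψ = 1 the cryptic junction's norm_score is ≈ 1.
Reads are single-end, uniform 100 bp, error-free, with anchors ≥ 20 and
correct `aMbNcM` CIGARs; the generator can also emit per-sample junction
BED12 directly, which feeds the same cohort machinery and keeps cohort-scale
experiments fast. All randomness flows from one seed through a single
generator.

What the generator does **not** emulate: realistic expression distributions,
paired-end fragments, sequencing error, alignment ambiguity, multi-isoform
genes, or germline contamination. Passing tests therefore demonstrate the
correctness of the coordinate arithmetic, classification logic and statistics
under the stated generative model — not robustness to alignment artifacts in
real tumor data.

## Study conditions used by the tests and the acceptance script

- Default cohort: 3 genes × 3 exons, 20 samples, 5 variant-carrying, depth 50
  molecules/gene, effect fraction 0.5, SAM emission.
- Null calibration: 300 genes with zero-effect variants, baseline alternative
  usage 0.5, one variant sample per cohort of 20, depth 120, BED emission;
  with 19 non-variant samples the discrete p-value attains 0 with
  probability 1/20 under exchangeability, so the α = 0.05 exceedance is
  calibrated up to ties.
- Power/ranking: 20 seeds of 51 genes (1 effect gene at fraction 0.5 + 50
  null genes at baseline usage 0.1), 5/20 variant samples, depth 50.

These sizes keep the full suite under a minute while leaving every
statistical check at its stated resolution.

## Known limitations

- Multi-allelic and symbolic/structural alleles are rejected (with a
  warning), not interpreted.
- Gene assignment for variants relies on transcript span overlap; nested or
  antisense-overlapping genes all receive annotations, and prioritization is
  left to downstream consumers.
- The footprint/classifier terminal-edge mismatch described above.
- Recurrence ranks genes; it applies no multiple-testing control across
  genes.
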