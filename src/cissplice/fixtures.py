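"""Synthetic reference and cohort generator.

Emulates the data model the statistical machinery expects: multi-exon genes
with canonical GT-AG introns on a random genome, RNA-seq reads spanning
canonical and cryptic junctions (correct ``aMbNcM`` CIGARs), and cohorts in
which a subset of samples carries a variant at an exon edge that reroutes a
stated fraction of transcript molecules to a non-reference junction (an
exon skip or a cryptic donor).  All randomness flows from one seed through
a single generator.

The generative model per gene and sample: ``depth`` transcript molecules
are drawn; a binomial split with the sample's rerouted fraction decides how
many molecules follow the cryptic isoform; each junction's read count is
then a binomial(2*molecules, 1/2) depth-noise draw.  With full rerouting a
variant sample therefore shows norm_score ~ 1.0 at the cryptic junction.

Reads are single-end, uniform length, error-free; no operation downstream
depends on base qualities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .junctions_extract import Junction, write_bed12
from .reference_model import (
    GenomeSequence,
    GenomicInterval,
    TranscriptModel,
    TranscriptomeIndex,
    write_gtf,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 3
    exons_per_gene: int = 3
    exon_length: tuple[int, int] = (80, 200)
    intron_length: tuple[int, int] = (100, 300)
    gene_spacing: int = 500
    alternate_strands: bool = True
    n_samples: int = 20
    n_variant_samples: int = 5
    read_depth: int = 50  # transcript molecules per gene per sample
    read_length: int = 100
    effect_fraction: float = 0.5  # rerouted fraction in variant samples
    baseline_alt_fraction: float = 0.0  # cryptic usage in every sample
    n_effect_genes: int = 1
    null_variants: bool = False  # plant zero-effect variants in other genes
    variant_offset: int = 2  # intronic bases from the acceptor-side exon edge
    cryptic_kind: str = "exon_skip"  # or "cryptic_donor"
    cryptic_donor_shift: int = 15
    contig: str = "chr1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")
        if not 0.0 <= self.baseline_alt_fraction <= 1.0:
            raise ValueError("baseline_alt_fraction must lie in [0, 1]")
        if self.n_variant_samples > self.n_samples:
            raise ValueError("n_variant_samples must be <= n_samples")
        if self.exons_per_gene < 3 and self.cryptic_kind == "exon_skip":
            raise ValueError("exon skipping needs at least 3 exons per gene")
        if self.exon_length[0] > self.exon_length[1] or self.intron_length[0] > self.intron_length[1]:
            raise ValueError("infeasible length ranges")
        if self.cryptic_kind not in ("exon_skip", "cryptic_donor"):
            raise ValueError("cryptic_kind must be exon_skip or cryptic_donor")
        if self.exon_length[0] < 30 or self.intron_length[0] < 70:
            raise ValueError(
                "exons must be >= 30 bp and introns >= 70 bp so reads anchor "
                "and junctions pass the default intron filter"
            )


@dataclass(frozen=True)
class PlantedEvent:
    gene_id: str
    contig: str
    variant_pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    cryptic_start: int
    cryptic_end: int
    source_intron: int
    expected_type: str
    effect_fraction: float
    variant_samples: tuple[str, ...]


@dataclass
class ReferenceBundle:
    fasta_path: Path
    gtf_path: Path
    contig: str
    sequence: str
    transcripts: list[TranscriptModel]

    @property
    def index(self) -> TranscriptomeIndex:
        return TranscriptomeIndex(self.transcripts)

    @property
    def genome(self) -> GenomeSequence:
        return GenomeSequence.from_dict({self.contig: self.sequence})


@dataclass
class CohortBundle:
    outdir: Path
    manifest_path: Path
    truth_path: Path
    sample_ids: list[str]
    sample_paths: dict[str, tuple[Path, Path]]  # id -> (junction source, vcf)
    truth: list[PlantedEvent]
    reference: ReferenceBundle


def _write_fasta(path: Path, contig: str, sequence: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), 80):
            fh.write(sequence[i : i + 80] + "\n")


def make_reference(
    config: SimulationConfig, outdir: str | Path
) -> ReferenceBundle:
    """Random genome + GTF with canonical GT-AG introns; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = []
    layout: list[list[GenomicInterval]] = []
    cursor = max(config.gene_spacing, config.read_length + 10)
    for g in range(config.n_genes):
        strand = "-" if (config.alternate_strands and g % 2) else "+"
        exons = []
        for e in range(config.exons_per_gene):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append(GenomicInterval(config.contig, cursor, cursor + length, strand))
            cursor += length
            if e < config.exons_per_gene - 1:
                cursor += int(
                    rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                )
        gene_id = f"G{g:03d}"
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}T1",
                gene_id=gene_id,
                gene_name=f"GENE{g}",
                strand=strand,
                exons=tuple(exons),
            )
        )
        layout.append(exons)
        cursor += config.gene_spacing
    total_len = cursor + config.gene_spacing
    seq = rng.choice(_BASES, size=total_len)
    for tx in transcripts:
        for intron in tx.introns():
            if tx.strand == "+":
                left, right = "GT", "AG"
            else:
                left, right = "CT", "AC"  # reverse complement of GT-AG
            seq[intron.start : intron.start + 2] = list(left)
            seq[intron.end - 2 : intron.end] = list(right)
    sequence = "".join(seq)
    fasta_path = outdir / "reference.fa"
    gtf_path = outdir / "reference.gtf"
    _write_fasta(fasta_path, config.contig, sequence)
    with open(gtf_path, "w") as fh:
        write_gtf(transcripts, fh)
    return ReferenceBundle(fasta_path, gtf_path, config.contig, sequence, transcripts)


def _plan_events(
    config: SimulationConfig,
    reference: ReferenceBundle,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> list[PlantedEvent]:
    variant_samples = tuple(
        sorted(
            str(s)
            for s in rng.choice(
                sample_ids, size=config.n_variant_samples, replace=False
            )
        )
    ) if config.n_variant_samples else ()
    events = []
    for g, tx in enumerate(reference.transcripts):
        has_variant = g < config.n_effect_genes or config.null_variants
        if not has_variant:
            continue
        effect = config.effect_fraction if g < config.n_effect_genes else 0.0
        intron0 = tx.introns()[0]
        exons = tx.exons
        pos0 = intron0.end - config.variant_offset  # acceptor-side intronic base
        ref_base = reference.sequence[pos0]
        alt_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        if config.cryptic_kind == "exon_skip":
            c_start, c_end = exons[0].end, exons[2].start
            expected = "NDA"
        else:
            c_start = exons[0].end - config.cryptic_donor_shift
            c_end = exons[1].start
            expected = "A" if tx.strand == "+" else "D"
        events.append(
            PlantedEvent(
                gene_id=tx.gene_id,
                contig=reference.contig,
                variant_pos=pos0 + 1,
                ref=ref_base,
                alt=alt_base,
                cryptic_start=c_start,
                cryptic_end=c_end,
                source_intron=0,
                expected_type=expected,
                effect_fraction=effect,
                variant_samples=variant_samples,
            )
        )
    return events


def _sample_gene_counts(
    config: SimulationConfig,
    tx: TranscriptModel,
    event: Optional[PlantedEvent],
    is_variant_sample: bool,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """(intron_start, intron_end, reads) per expressed junction of one gene."""
    introns = tx.introns()
    depth = config.read_depth
    psi = config.baseline_alt_fraction
    if event is not None and is_variant_sample:
        psi = min(1.0, psi + event.effect_fraction)
    counts: dict[tuple[int, int], int] = {}
    if event is None or psi == 0.0:
        rerouted = 0
    else:
        rerouted = int(rng.binomial(depth, psi))
    canonical = depth - rerouted
    # junctions the cryptic isoform bypasses
    if event is not None and config.cryptic_kind == "exon_skip":
        bypassed = {0, 1}
    elif event is not None:
        bypassed = {0}
    else:
        bypassed = set()
    for k, intron in enumerate(introns):
        molecules = canonical if (k in bypassed and event is not None) else depth
        reads = int(rng.binomial(2 * molecules, 0.5)) if molecules else 0
        if reads:
            counts[(intron.start, intron.end)] = reads
    if event is not None and rerouted:
        reads = int(rng.binomial(2 * rerouted, 0.5))
        if reads:
            key = (event.cryptic_start, event.cryptic_end)
            counts[key] = counts.get(key, 0) + reads
    return [(s, e, n) for (s, e), n in sorted(counts.items())]


def _emit_sam(
    path: Path,
    contig: str,
    contig_len: int,
    gene_junction_counts: list[tuple[TranscriptModel, list[tuple[int, int, int]]]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    read_len = config.read_length
    reads = []
    for tx, counts in gene_junction_counts:
        for start, end, n in counts:
            for _ in range(n):
                left = int(rng.integers(20, read_len - 20 + 1))
                pos0 = start - left
                cigar = f"{left}M{end - start}N{read_len - left}M"
                reads.append((pos0, cigar, tx.strand))
    reads.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{contig_len}\n")
        for i, (pos0, cigar, strand) in enumerate(reads):
            fh.write(
                "\t".join(
                    [
                        f"r{i:06d}",
                        "0",
                        contig,
                        str(pos0 + 1),
                        "60",
                        cigar,
                        "*",
                        "0",
                        "0",
                        "*",
                        "*",
                        f"XS:A:{strand}",
                    ]
                )
                + "\n"
            )


def _emit_bed(
    path: Path,
    contig: str,
    gene_junction_counts: list[tuple[TranscriptModel, list[tuple[int, int, int]]]],
) -> None:
    anchor = 25
    junctions = []
    for _tx, counts in gene_junction_counts:
        for start, end, n in counts:
            junctions.append(
                Junction(
                    contig=contig,
                    intron_start=start,
                    intron_end=end,
                    strand=_tx.strand,
                    score=n,
                    thick_start=start - anchor,
                    thick_end=end + anchor,
                )
            )
    junctions.sort(key=lambda j: (j.intron_start, j.intron_end))
    with open(path, "w") as fh:
        write_bed12(junctions, fh)


def _emit_vcf(
    path: Path,
    contig: str,
    contig_len: int,
    variants: list[tuple[int, str, str]],
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in sorted(variants):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def simulate_cohort(
    reference: ReferenceBundle,
    config: SimulationConfig,
    outdir: str | Path,
    emit: str = "sam",
) -> CohortBundle:
    """Per-sample alignments (or junction BEDs) + VCFs + a truth table.

    ``emit="sam"`` writes reads with correct CIGARs; ``emit="bed"`` writes
    the per-sample junction counts directly as BED12, which is faster for
    cohort-scale experiments and feeds the same downstream machinery.
    """
    if emit not in ("sam", "bed"):
        raise ValueError("emit must be 'sam' or 'bed'")
    rng = np.random.default_rng(config.seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    events = _plan_events(config, reference, sample_ids, rng)
    if events and config.read_depth * max(
        (e.effect_fraction for e in events), default=0.0
    ) < 1 and config.n_effect_genes:
        warnings.warn("read depth too low to realize the effect fraction")
    event_by_gene = {e.gene_id: e for e in events}
    contig_len = len(reference.sequence)

    sample_paths: dict[str, tuple[Path, Path]] = {}
    truth_rows = events
    for sample_id in sample_ids:
        gene_counts = []
        variants: list[tuple[int, str, str]] = []
        for tx in reference.transcripts:
            event = event_by_gene.get(tx.gene_id)
            is_variant_sample = (
                event is not None and sample_id in event.variant_samples
            )
            if is_variant_sample:
                variants.append((event.variant_pos, event.ref, event.alt))
            gene_counts.append(
                (
                    tx,
                    _sample_gene_counts(
                        config, tx, event, is_variant_sample, rng
                    ),
                )
            )
        if emit == "sam":
            junc_path = outdir / f"{sample_id}.sam"
            _emit_sam(
                junc_path,
                reference.contig,
                contig_len,
                gene_counts,
                config,
                rng,
            )
        else:
            junc_path = outdir / f"{sample_id}.bed"
            _emit_bed(junc_path, reference.contig, gene_counts)
        vcf_path = outdir / f"{sample_id}.vcf"
        _emit_vcf(vcf_path, reference.contig, contig_len, variants)
        sample_paths[sample_id] = (junc_path, vcf_path)

    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        for sample_id in sample_ids:
            junc, vcf = sample_paths[sample_id]
            fh.write(f"{sample_id}\t{junc.name}\t{vcf.name}\n")
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "gene_id\tcontig\tvariant_pos\tref\talt\tcryptic_start\t"
            "cryptic_end\texpected_type\teffect_fraction\tvariant_samples\n"
        )
        for e in truth_rows:
            fh.write(
                f"{e.gene_id}\t{e.contig}\t{e.variant_pos}\t{e.ref}\t{e.alt}\t"
                f"{e.cryptic_start}\t{e.cryptic_end}\t{e.expected_type}\t"
                f"{e.effect_fraction}\t{','.join(e.variant_samples)}\n"
            )
    return CohortBundle(
        outdir=outdir,
        manifest_path=manifest_path,
        truth_path=truth_path,
        sample_ids=sample_ids,
        sample_paths=sample_paths,
        truth=truth_rows,
        reference=reference,
    )
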