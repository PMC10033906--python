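import io

import pandas as pd
import pytest

from cissplice import (
    GenomicInterval,
    IdentifyParams,
    SpliceVariantWindow,
    associate,
    associate_mode,
    classify_junction,
    classify_variant,
    extract_junctions,
    identify,
    make_reference,
    simulate_cohort,
    SimulationConfig,
    parse_gtf,
    GenomeSequence,
    splice_junction_region,
    variant_region,
    write_bed12,
)
from cissplice.cis_splice_effects import (
    SpliceJunctionRegion,
    associate as associate_op,
    events_table,
)
from cissplice.junctions_extract import Junction
from cissplice.variants_annotate import annotate_variant_tuple, annotate_variants

DEFAULT = SpliceVariantWindow()
ALL_INTRONIC = SpliceVariantWindow(all_intronic=True)


class TestSpliceJunctionRegion:
    def test_exonic_variant_in_middle_exon_spans_flanking_exons(self, toy_index):
        tx = toy_index.transcripts["TX1"]
        ann = classify_variant(350, tx, DEFAULT)  # plain exonic in exon 2
        region = splice_junction_region(ann, tx, 350)
        assert (region.start, region.end) == (200, 500)

    def test_plain_intronic_variant_limited_to_containing_intron(self, toy_index):
        tx = toy_index.transcripts["TX1"]
        ann = classify_variant(250, tx, ALL_INTRONIC)
        region = splice_junction_region(ann, tx, 250)
        assert (region.start, region.end) == (200, 300)

    def test_splicing_intronic_variant_uses_nearest_edge_exon(self, toy_index):
        tx = toy_index.transcripts["TX1"]
        ann = classify_variant(298, tx, DEFAULT)  # 2 bases from exon 2 start
        assert ann.variant_type == "splicing_intronic"
        region = splice_junction_region(ann, tx, 298)
        assert (region.start, region.end) == (200, 500)

    def test_first_exon_clamps_to_transcript_start(self, toy_index):
        tx = toy_index.transcripts["TX1"]
        ann = classify_variant(150, tx, DEFAULT)
        region = splice_junction_region(ann, tx, 150)
        assert (region.start, region.end) == (100, 300)

    def test_last_exon_clamps_to_transcript_end(self, toy_index):
        tx = toy_index.transcripts["TX1"]
        ann = classify_variant(550, tx, DEFAULT)
        region = splice_junction_region(ann, tx, 550)
        assert (region.start, region.end) == (400, 600)

    def test_window_override_centers_on_variant(self, toy_index):
        tx = toy_index.transcripts["TX1"]
        ann = classify_variant(350, tx, DEFAULT)
        region = splice_junction_region(ann, tx, 350, w_override=100)
        assert (region.start, region.end) == (300, 400)
        with pytest.raises(ValueError):
            splice_junction_region(ann, tx, 350, w_override=1)

    def test_variant_region_union_over_transcripts(self, toy_index):
        """With no splice-relevant annotation there is no region; otherwise
        the union span over contributing transcripts is used."""
        plain = annotate_variant_tuple("chr1", 351, "A", "C", toy_index, DEFAULT)
        assert variant_region(plain, toy_index, DEFAULT) is None
        splice = annotate_variant_tuple("chr1", 302, "A", "C", toy_index, DEFAULT)
        region = variant_region(splice, toy_index, DEFAULT)
        assert (region.start, region.end) == (200, 500)

    def test_enlarging_window_never_removes_a_region(self, toy_index):
        small = SpliceVariantWindow(intronic_bases=2, exonic_bases=3)
        big = SpliceVariantWindow(intronic_bases=20, exonic_bases=10)
        tx = toy_index.transcripts["TX1"]
        for pos0 in range(tx.span.start, tx.span.end):
            v = annotate_variant_tuple("chr1", pos0 + 1, "A", "C", toy_index, small)
            if variant_region(v, toy_index, small) is not None:
                v_big = annotate_variant_tuple(
                    "chr1", pos0 + 1, "A", "C", toy_index, big
                )
                assert variant_region(v_big, toy_index, big) is not None


def make_junction(start, end, strand="?"):
    return Junction(
        contig="chr1", intron_start=start, intron_end=end, strand=strand,
        score=5, thick_start=start - 20, thick_end=end + 20,
    )


class TestAssociate:
    def test_overlap_and_halfopen_abutment(self, toy_index):
        variant = annotate_variant_tuple("chr1", 302, "A", "C", toy_index, DEFAULT)
        region = variant_region(variant, toy_index, DEFAULT)  # [200, 500)
        regions = [SpliceJunctionRegion(variant, region)]
        inside = classify_junction(make_junction(200, 500), toy_index)
        abutting = classify_junction(make_junction(120, 200), toy_index)
        events = associate_op(regions, [inside, abutting])
        assert len(events) == 1
        assert events[0].junction.junction.intron_start == 200

    def test_one_variant_three_junctions_three_events(self, toy_index):
        variant = annotate_variant_tuple("chr1", 302, "A", "C", toy_index, DEFAULT)
        region = variant_region(variant, toy_index, DEFAULT)
        regions = [SpliceJunctionRegion(variant, region)]
        juncs = [
            classify_junction(make_junction(s, e), toy_index)
            for s, e in ((200, 300), (200, 500), (400, 500))
        ]
        events = associate_op(regions, juncs)
        assert len(events) == 3
        table = events_table(events)
        assert list(table["variant_pos"].unique()) == [302]

    def test_empty_inputs_give_empty_output(self):
        assert associate_op([], []) == []


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    cfg = SimulationConfig(seed=9)
    d = tmp_path_factory.mktemp("sim")
    ref = make_reference(cfg, d)
    cohort = simulate_cohort(ref, cfg, d, emit="sam")
    index = parse_gtf(ref.gtf_path)
    genome = GenomeSequence.from_fasta(ref.fasta_path)
    return cfg, ref, cohort, index, genome


class TestIdentify:
    def test_recovers_planted_event(self, sim):
        cfg, ref, cohort, index, genome = sim
        truth = cohort.truth[0]
        sample = truth.variant_samples[0]
        sam, vcf = cohort.sample_paths[sample]
        table = identify(str(vcf), str(sam), index, genome)
        hits = table[
            (table["start"] == truth.cryptic_start)
            & (table["end"] == truth.cryptic_end)
        ]
        assert len(hits) == 1
        assert hits.iloc[0]["anchor"] == truth.expected_type
        assert hits.iloc[0]["variant_pos"] == truth.variant_pos

    def test_no_splice_relevant_variants_gives_empty_table(self, sim, tmp_path):
        cfg, ref, cohort, index, genome = sim
        sample = cohort.truth[0].variant_samples[0]
        sam, _ = cohort.sample_paths[sample]
        vcf = tmp_path / "none.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={ref.contig}>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        table = identify(str(vcf), str(sam), index, genome)
        assert len(table) == 0

    def test_identify_equals_manual_composition_byte_identical(self, sim):
        """identify == annotate variants -> extract -> annotate junctions ->
        associate, run step by step, byte-for-byte on the TSV."""
        cfg, ref, cohort, index, genome = sim
        sample = cohort.truth[0].variant_samples[0]
        sam, vcf = cohort.sample_paths[sample]
        pipeline = identify(str(vcf), str(sam), index, genome)

        window = SpliceVariantWindow()
        annotated = annotate_variants(str(vcf), index, window)
        regions = []
        for v in annotated:
            region = variant_region(v, index, window)
            if region is not None:
                regions.append(SpliceJunctionRegion(v, region))
        junctions = extract_junctions(str(sam))
        annotated_junctions = [classify_junction(j, index, genome) for j in junctions]
        manual = events_table(associate_op(regions, annotated_junctions))

        assert pipeline.to_csv(sep="\t", index=False) == manual.to_csv(
            sep="\t", index=False
        )

    def test_associate_mode_on_extract_output_equals_identify(self, sim, tmp_path):
        cfg, ref, cohort, index, genome = sim
        sample = cohort.truth[0].variant_samples[0]
        sam, vcf = cohort.sample_paths[sample]
        bed = tmp_path / "juncs.bed"
        with open(bed, "w") as fh:
            write_bed12(extract_junctions(str(sam)), fh)
        from_bed = associate_mode(str(vcf), str(bed), index, genome)
        from_sam = identify(str(vcf), str(sam), index, genome)
        assert from_bed.to_csv(sep="\t", index=False) == from_sam.to_csv(
            sep="\t", index=False
        )

    def test_empty_bed_gives_empty_events(self, sim, tmp_path):
        cfg, ref, cohort, index, genome = sim
        sample = cohort.truth[0].variant_samples[0]
        _, vcf = cohort.sample_paths[sample]
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert len(associate_mode(str(vcf), str(bed), index, genome)) == 0

    def test_sidecar_outputs_written(self, sim, tmp_path):
        cfg, ref, cohort, index, genome = sim
        sample = cohort.truth[0].variant_samples[0]
        sam, vcf = cohort.sample_paths[sample]
        v_out = tmp_path / "annotated.vcf"
        j_out = tmp_path / "regional.bed"
        identify(
            str(vcf), str(sam), index, genome,
            variant_out=str(v_out), junctions_out=str(j_out),
        )
        assert "variant_types" in v_out.read_text()
        assert j_out.read_text().count("\n") >= 1
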