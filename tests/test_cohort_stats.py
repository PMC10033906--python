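import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cissplice import (
    GenomicInterval,
    SimulationConfig,
    SpliceVariantWindow,
    benjamini_hochberg,
    compare_junctions,
    empirical_p_value,
    load_cohort_manifest,
    make_reference,
    norm_score,
    parse_gtf,
    simulate_cohort,
)
from cissplice.cohort_stats import REFERENCE_CLASSES, CohortSample
from cissplice.junctions_extract import Junction


def make_junction(start, end, score, strand="+"):
    return Junction(
        contig="chr1", intron_start=start, intron_end=end, strand=strand,
        score=score, thick_start=start - 20, thick_end=end + 20,
    )


class TestNormScore:
    def test_only_junction_in_region(self):
        region = GenomicInterval("chr1", 100, 500)
        j = make_junction(150, 250, 10)
        assert norm_score(j.key, region, [j]) == 1.0

    def test_fraction_of_region_total(self):
        region = GenomicInterval("chr1", 100, 500)
        js = [make_junction(150, 250, 5), make_junction(150, 400, 15)]
        assert norm_score(js[0].key, region, js) == 0.25

    def test_absent_junction_and_empty_region(self):
        region = GenomicInterval("chr1", 100, 500)
        outside = make_junction(700, 800, 50)
        assert norm_score(("chr1", 150, 250, "+"), region, [outside]) == 0.0
        assert norm_score(("chr1", 150, 250, "+"), region, []) == 0.0

    def test_scores_sum_to_one_per_region_per_sample(self):
        rng = np.random.default_rng(2)
        region = GenomicInterval("chr1", 0, 10_000)
        js = [
            make_junction(
                int(s), int(s) + int(rng.integers(70, 900)), int(rng.integers(1, 50))
            )
            for s in rng.integers(0, 9000, size=20)
        ]
        total = sum(norm_score(j.key, region, js) for j in js)
        assert total == pytest.approx(1.0)


class TestEmpiricalPValue:
    def test_ties_count_toward_p(self):
        assert empirical_p_value(0.5, [0.1, 0.2, 0.5, 0.6]) == 0.5

    def test_mean_zero_gives_p_one(self):
        assert empirical_p_value(0.0, [0.0, 0.1, 0.3]) == 1.0

    def test_no_null_samples_is_nan(self):
        assert math.isnan(empirical_p_value(0.5, []))

    def test_matches_brute_force_counting_on_random_cohorts(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            m = int(rng.integers(1, 30))
            scores = rng.random(m).round(2).tolist()
            mean = round(float(rng.random()), 2)
            expected = sum(s >= mean for s in scores) / m
            assert empirical_p_value(mean, scores) == expected
            # attainable values are k/m
            assert empirical_p_value(mean, scores) * m == pytest.approx(
                round(empirical_p_value(mean, scores) * m)
            )


def bh_oracle(pvals):
    """Textbook step-up: p_(i) * n / i with right-to-left cummin, capped at 1."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adjusted[i] = running
    return adjusted


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.031])[0] == pytest.approx(0.031)

    def test_textbook_example(self):
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        assert np.allclose(benjamini_hochberg([0.2, 0.2, 0.2]), 0.2)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, math.nan])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            p = rng.random(n).tolist()
            assert np.allclose(benjamini_hochberg(p), bh_oracle(p))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_permutation_invariant_and_never_below_raw_over_n(self, p):
        adjusted = benjamini_hochberg(p)
        assert np.all(adjusted >= np.asarray(p) / len(p) - 1e-12)
        perm = np.random.RandomState(0).permutation(len(p))
        adj_perm = benjamini_hochberg([p[i] for i in perm])
        assert np.allclose(np.asarray(adjusted)[perm], adj_perm)
        assert np.all(adjusted >= np.asarray(p) - 1e-12)


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    cfg = SimulationConfig(seed=21, n_genes=4, null_variants=True,
                           baseline_alt_fraction=0.1)
    d = tmp_path_factory.mktemp("cohort")
    ref = make_reference(cfg, d)
    bundle = simulate_cohort(ref, cfg, d, emit="bed")
    index = parse_gtf(ref.gtf_path)
    samples = load_cohort_manifest(bundle.manifest_path)
    return cfg, bundle, index, samples


class TestCompareJunctions:
    def test_planted_event_significant_and_types_filtered(self, cohort):
        cfg, bundle, index, samples = cohort
        table = compare_junctions(samples, index)
        assert set(table["junction_type"]) <= {"D", "A", "NDA"}
        truth = bundle.truth[0]
        hit = table[
            (table["variant_pos"] == truth.variant_pos)
            & (table["junction_start"] == truth.cryptic_start)
            & (table["junction_end"] == truth.cryptic_end)
        ]
        assert len(hit) == 1
        assert bool(hit.iloc[0]["significant"])
        assert hit.iloc[0]["n_variant_samples"] == cfg.n_variant_samples

    def test_da_analysis_selects_known_junctions(self, cohort):
        cfg, bundle, index, samples = cohort
        table = compare_junctions(samples, index, junction_classes=REFERENCE_CLASSES)
        assert set(table["junction_type"]) <= {"DA"}
        assert len(table) > 0

    def test_min_read_filter_excludes_weak_events(self, cohort):
        cfg, bundle, index, samples = cohort
        table = compare_junctions(samples, index, min_reads=5)
        assert (table["total_variant_reads"] >= 5).all()
        huge = compare_junctions(samples, index, min_reads=10**9)
        assert len(huge) == 0

    def test_chunking_does_not_change_any_statistic(self, cohort):
        cfg, bundle, index, samples = cohort
        whole = compare_junctions(samples, index)
        chunked = compare_junctions(samples, index, chunk_size=1)
        pd.testing.assert_frame_equal(whole, chunked)

    def test_mean_norm_score_for_single_variant_sample(self, cohort):
        """With one variant-containing sample the mean equals its norm_score."""
        cfg, bundle, index, samples = cohort
        truth = bundle.truth[0]
        keep = truth.variant_samples[:1]
        trimmed = [
            s
            for s in samples
            if s.sample_id in keep or s.sample_id not in truth.variant_samples
        ]
        table = compare_junctions(trimmed, index)
        hit = table[
            (table["variant_pos"] == truth.variant_pos)
            & (table["junction_start"] == truth.cryptic_start)
        ].iloc[0]
        sample = next(s for s in trimmed if s.sample_id == keep[0])
        region = GenomicInterval("chr1", int(hit["region_start"]), int(hit["region_end"]))
        expected = norm_score(
            ("chr1", truth.cryptic_start, truth.cryptic_end, hit["junction_strand"]),
            region,
            sample.junctions,
        )
        assert hit["mean_norm_score"] == pytest.approx(expected)
        assert hit["n_variant_samples"] == 1

    def test_empty_cohort_rejected(self, cohort):
        cfg, bundle, index, samples = cohort
        with pytest.raises(ValueError, match="empty cohort"):
            compare_junctions([], index)

    def test_norm_scores_match_brute_force_over_all_samples(self, cohort):
        """Event p-values equal direct >=-counting over per-sample scores
        recomputed from raw junction lists."""
        cfg, bundle, index, samples = cohort
        table = compare_junctions(samples, index)
        for _, row in table.iterrows():
            region = GenomicInterval(
                "chr1", int(row["region_start"]), int(row["region_end"])
            )
            key = (
                "chr1",
                int(row["junction_start"]),
                int(row["junction_end"]),
                row["junction_strand"],
            )
            variant_ids = set(str(row["variant_samples"]).split(","))
            scores = {
                s.sample_id: norm_score(key, region, s.junctions) for s in samples
            }
            v_scores = [scores[s] for s in scores if s in variant_ids]
            n_scores = [scores[s] for s in scores if s not in variant_ids]
            mean = sum(v_scores) / len(v_scores)
            assert row["mean_norm_score"] == pytest.approx(mean)
            expected_p = sum(s >= mean for s in n_scores) / len(n_scores)
            assert row["p_value"] == pytest.approx(expected_p)
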