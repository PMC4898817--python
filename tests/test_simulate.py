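"""Synthetic-data generators: determinism, geometry, truth consistency."""

import math

import numpy as np
import pytest

from morna import (
    Category,
    DeClass,
    DeSimConfig,
    SimConfig,
    UtrSimConfig,
    build_locus_index,
    classify_de,
    derive_regions,
    find_candidate_loci,
    gen_annotation,
    gen_de_table,
    gen_utrs,
    scan_utrs,
    simulate_reads,
)
from morna.quant import classify
from morna.seeds import SeedWindow


PLANTED = SeedWindow(2, "UGUACCA")  # pattern TGGTACA


class TestGenAnnotation:
    def test_single_locus_yields_four_windows(self):
        bundle = gen_annotation(SimConfig(seed=3, n_loci=1))
        (locus,) = bundle.loci
        rs = derive_regions(locus)
        assert None not in (rs.mir5p_win, rs.mir3p_win, rs.mor5p_win, rs.mor3p_win)

    def test_same_seed_is_byte_identical(self):
        a = gen_annotation(SimConfig(seed=11))
        b = gen_annotation(SimConfig(seed=11))
        assert a.genome == b.genome
        assert a.loci == b.loci

    def test_different_seed_differs(self):
        a = gen_annotation(SimConfig(seed=11))
        b = gen_annotation(SimConfig(seed=12))
        assert a.genome != b.genome

    def test_fifty_loci_pairwise_spacing(self):
        bundle = gen_annotation(SimConfig(seed=5, n_loci=50, chrom_length=1_000_000))
        assert len(bundle.loci) == 50
        ivs = [l.interval for l in bundle.loci]
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                assert ivs[i].gap_to(ivs[j]) >= 200

    def test_infeasible_packing_errors(self):
        with pytest.raises(ValueError, match="pack"):
            gen_annotation(SimConfig(seed=1, n_loci=100, chrom_length=5_000))

    def test_close_pairs_only_when_requested(self):
        none = gen_annotation(SimConfig(seed=2))
        some = gen_annotation(SimConfig(seed=2, multi_locus_fraction=0.1))
        assert none.close_pairs == []
        assert len(some.close_pairs) >= 1


class TestSimulateReads:
    def test_pure_mir5p_mix_classifies_perfectly(self):
        mix = {"MIR5P": 1.0, "MIR3P": 0.0, "MOR5P": 0.0, "MOR3P": 0.0,
               "BACKGROUND": 0.0}
        config = SimConfig(seed=7, n_loci=5, reads_per_library=500, category_mix=mix)
        bundle = gen_annotation(config)
        segments, truths = simulate_reads(config, bundle)
        regions = {l.id: derive_regions(l) for l in bundle.loci}
        for seg, truth in zip(segments, truths):
            assert truth.category is Category.MIR5P
            assert classify(seg, regions[truth.locus_id]) is Category.MIR5P

    def test_background_reads_have_no_candidate_loci(self):
        mix = {"MIR5P": 0.0, "MIR3P": 0.0, "MOR5P": 0.0, "MOR3P": 0.0,
               "BACKGROUND": 1.0}
        config = SimConfig(seed=8, n_loci=5, reads_per_library=300, category_mix=mix)
        bundle = gen_annotation(config)
        segments, truths = simulate_reads(config, bundle)
        index = build_locus_index(bundle.loci)
        assert all(t.locus_id is None for t in truths)
        for seg in segments:
            assert find_candidate_loci(seg, index) == set()

    def test_category_shares_within_sampling_error(self):
        """Weighted category shares track the configured mix within 4 SE."""
        mix = {"MIR5P": 0.4, "MIR3P": 0.3, "MOR5P": 0.2, "MOR3P": 0.1,
               "BACKGROUND": 0.0}
        n = 20_000
        config = SimConfig(seed=9, reads_per_library=n, category_mix=mix)
        bundle = gen_annotation(config)
        _, truths = simulate_reads(config, bundle)
        counts = {c: 0 for c in mix}
        for t in truths:
            counts[t.category.value] += 1
        for cat, p in mix.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[cat] / n - p) < 4 * se + 1e-12

    def test_truth_labels_recovered_for_single_locus_reads(self):
        config = SimConfig(seed=10, reads_per_library=2_000)
        bundle = gen_annotation(config)
        segments, truths = simulate_reads(config, bundle)
        regions = {l.id: derive_regions(l) for l in bundle.loci}
        for seg, truth in zip(segments, truths):
            if truth.locus_id is None or truth.multi_locus:
                continue
            assert classify(seg, regions[truth.locus_id]) is truth.category

    def test_multi_locus_reads_near_two_hairpins(self):
        config = SimConfig(seed=4, reads_per_library=500, multi_locus_fraction=0.3)
        bundle = gen_annotation(config)
        segments, truths = simulate_reads(config, bundle)
        index = build_locus_index(bundle.loci)
        n_multi = 0
        for seg, truth in zip(segments, truths):
            if truth.multi_locus:
                n_multi += 1
                assert len(find_candidate_loci(seg, index)) == 2
        assert n_multi > 0

    def test_determinism(self):
        config = SimConfig(seed=6, reads_per_library=200)
        bundle = gen_annotation(config)
        a = simulate_reads(config, bundle)
        b = simulate_reads(config, bundle)
        assert a == b


class TestGenUtrs:
    def test_plant_rate_one_hits_every_gene(self):
        config = UtrSimConfig(seed=1, n_genes=80, planted_window=PLANTED,
                              plant_rate=1.0)
        utrs, truth = gen_utrs(config)
        ts = scan_utrs(PLANTED, utrs)
        assert set(ts.hits) == {u.gene_id for u in utrs}
        for t in truth:
            assert t.planted and t.plant_offset is not None

    def test_planted_offset_recorded_correctly(self):
        config = UtrSimConfig(seed=2, n_genes=50, planted_window=PLANTED,
                              plant_rate=1.0)
        utrs, truth = gen_utrs(config)
        for utr, t in zip(utrs, truth):
            assert utr.seq[t.plant_offset:t.plant_offset + 7] == PLANTED.pattern

    def test_background_hit_rate_matches_closed_form(self):
        """With no planting, per-gene hit probability is 1-(1-4^-7)^(L-6)."""
        n, L = 500, 1000
        config = UtrSimConfig(seed=3, n_genes=n, utr_len=(L, L),
                              planted_window=PLANTED, plant_rate=0.0)
        utrs, _ = gen_utrs(config)
        rate = len(scan_utrs(PLANTED, utrs).hits) / n
        p = 1 - (1 - 0.25**7) ** (L - 6)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 4 * se

    def test_same_seed_identical(self):
        config = UtrSimConfig(seed=5, n_genes=30, planted_window=PLANTED)
        assert gen_utrs(config) == gen_utrs(config)


class TestGenDeTable:
    def test_intended_classes_recovered_exactly(self):
        utr_cfg = UtrSimConfig(seed=6, n_genes=400, planted_window=PLANTED)
        _, gene_truth = gen_utrs(utr_cfg)
        records, truths = gen_de_table(DeSimConfig(seed=6), gene_truth)
        for record, truth in zip(records, truths):
            assert classify_de(record).value == truth.intended_class

    def test_extreme_effect_makes_all_planted_detected_down(self):
        utr_cfg = UtrSimConfig(seed=7, n_genes=300, planted_window=PLANTED,
                               plant_rate=0.2)
        _, gene_truth = gen_utrs(utr_cfg)
        config = DeSimConfig(seed=7, p_down_target=1.0, p_down_background=0.0,
                             p_up=0.0, detected_rate=1.0)
        records, _ = gen_de_table(config, gene_truth)
        table = {r.gene_id: r for r in records}
        for gt in gene_truth:
            expected = DeClass.DOWN if gt.planted else DeClass.UNCHANGED
            assert classify_de(table[gt.gene_id]) is expected

    def test_determinism(self):
        _, gene_truth = gen_utrs(UtrSimConfig(seed=8, n_genes=100,
                                              planted_window=PLANTED))
        assert gen_de_table(DeSimConfig(seed=8), gene_truth) == gen_de_table(
            DeSimConfig(seed=8), gene_truth
        )

    def test_regulated_ranges_must_pass_thresholds(self):
        with pytest.raises(ValueError):
            DeSimConfig(fc_magnitude=(1.2, 2.0))
        with pytest.raises(ValueError):
            DeSimConfig(adjp_regulated=(1e-4, 0.01))


def test_invalid_category_mix_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(category_mix={"MIR5P": 0.5, "MIR3P": 0.2, "MOR5P": 0.1,
                                "MOR3P": 0.1, "BACKGROUND": 0.05})


def test_rng_streams_are_independent():
    """Annotation and read streams do not interact across configs."""
    a = gen_annotation(SimConfig(seed=1, n_loci=3))
    b = gen_annotation(SimConfig(seed=1, n_loci=3))
    np.testing.assert_array_equal(
        [l.interval.start for l in a.loci], [l.interval.start for l in b.loci]
    )
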