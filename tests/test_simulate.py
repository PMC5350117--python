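"""Synthetic-data generator: determinism, planted structure, recovery."""

import numpy as np
import pytest

from panelval.concordance import GenotypeClass as G, metrics_for_pair
from panelval.coverage import coverage_summary, extract_low_coverage_loci
from panelval.regions import RegionIndex
from panelval.simulate import (SimulationConfig, make_reference_panel,
                               simulate_depth, simulate_eval,
                               simulate_replicates, simulate_truth)
from panelval.variability import classify_pair, pairwise_metrics


SMALL = dict(n_genes=10, n_truth_variants=400)


class TestGeometry:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=1, n_genes=5)
        a = make_reference_panel(cfg)
        b = make_reference_panel(cfg)
        assert a.targets == b.targets and a.segdups == b.segdups

    def test_targets_disjoint_and_padded(self):
        ref = make_reference_panel(SimulationConfig(seed=2, **SMALL))
        ordered = sorted(ref.targets)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start
        # splice padding widens every exon by 2 nt each side
        lo, hi = SimulationConfig().exon_length
        assert all(lo + 4 <= t.length <= hi + 4 for t in ordered)

    def test_gene_count_matches_config(self):
        ref = make_reference_panel(SimulationConfig(seed=3, n_genes=61))
        assert ref.panel.gene_count() == 61

    def test_segdup_fraction_zero_means_none(self):
        ref = make_reference_panel(SimulationConfig(seed=1, segdup_fraction=0))
        assert ref.segdups == []

    def test_segdup_fraction_marks_some(self):
        ref = make_reference_panel(
            SimulationConfig(seed=1, n_genes=20, segdup_fraction=0.1))
        assert len(ref.segdups) > 0


class TestTruth:
    def test_zero_variants_empty_callset_full_regions(self):
        cfg = SimulationConfig(seed=4, n_genes=5, n_truth_variants=0)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        assert truth.calls == {}
        assert len(truth.assessed_regions) == len(ref.targets)

    def test_variants_contained_and_collision_free(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        index = ref.index
        assert len(truth.calls) == cfg.n_truth_variants
        positions = [(k.chrom, k.pos) for k in truth.calls]
        assert len(set(positions)) == len(positions)
        assert all(index.contains(c, p) for c, p in positions)

    def test_het_fraction_binomial(self):
        cfg = SimulationConfig(seed=6, n_genes=12, n_truth_variants=500,
                               het_fraction=0.6)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        n_het = sum(g is G.HET for g in truth.calls.values())
        se = np.sqrt(500 * 0.6 * 0.4)
        assert abs(n_het - 300) <= 3 * se

    def test_requesting_more_variants_than_bases_fails(self):
        cfg = SimulationConfig(seed=1, n_genes=1, exons_per_gene=(1, 1),
                               n_truth_variants=10**6)
        ref = make_reference_panel(cfg)
        with pytest.raises(ValueError):
            simulate_truth(ref.targets, cfg)


class TestEval:
    def test_zero_error_rates_identity(self):
        cfg = SimulationConfig(seed=7, fp_rate=0, fn_rate=0,
                               genotype_error_rate=0, **SMALL)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        eval_ = simulate_eval(truth, cfg)
        assert eval_.calls == truth.calls
        m = metrics_for_pair(truth, eval_, ref.index)
        assert (m.ogc, m.fp_rate, m.fn_rate) == (1.0, 0.0, 0.0)

    def test_forced_genotype_flips_keep_nrs_kill_nrgc(self):
        cfg = SimulationConfig(seed=8, fp_rate=0, fn_rate=0,
                               genotype_error_rate=1.0, **SMALL)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        eval_ = simulate_eval(truth, cfg)
        m = metrics_for_pair(truth, eval_, ref.index)
        assert m.nrs == 1.0      # every variant still detected non-ref
        assert m.nrgc == 0.0     # but no genotype matches exactly
        assert m.ogc == 0.0      # all co-called sites discordant

    def test_planted_rates_recovered_within_3se(self):
        cfg = SimulationConfig(seed=9, n_genes=61, n_truth_variants=5000,
                               fp_rate=0.07, fn_rate=0.04)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        eval_ = simulate_eval(truth, cfg)
        m = metrics_for_pair(truth, eval_, ref.index)
        n = cfg.n_truth_variants
        se_fp = np.sqrt(0.07 * 0.93 / n)
        se_fn = np.sqrt(0.04 * 0.96 / n)
        assert abs(m.fp_rate - 0.07) <= 3 * se_fp
        assert abs(m.fn_rate - 0.04) <= 3 * se_fn

    def test_empty_truth_rejected(self):
        cfg = SimulationConfig(seed=1, n_genes=2, n_truth_variants=0)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        with pytest.raises(ValueError):
            simulate_eval(truth, cfg)


class TestDepth:
    def test_high_mean_gives_full_coverage(self):
        cfg = SimulationConfig(seed=10, n_genes=5, mean_depth_1plex=400,
                               first_exon_depth_multiplier=1.0)
        ref = make_reference_panel(cfg)
        track = simulate_depth(ref.targets, cfg, plex=1)
        s = coverage_summary(track, ref.targets, threshold=15)
        assert s.frac_bases_ge_t > 0.999

    def test_plex_means_recovered_within_5pct(self):
        cfg = SimulationConfig(seed=11, n_genes=61)
        ref = make_reference_panel(cfg)
        assert ref.index.total_bases() >= 50_000
        for plex, mean in ((1, cfg.mean_depth_1plex),
                           (3, cfg.mean_depth_3plex)):
            track = simulate_depth(ref.targets, cfg, plex=plex)
            s = coverage_summary(track, ref.targets, threshold=15)
            assert abs(s.mean_depth - mean) / mean < 0.05

    def test_low_coverage_concentrates_in_first_exon(self):
        cfg = SimulationConfig(seed=12, n_genes=20,
                               first_exon_depth_multiplier=0.1,
                               mean_depth_1plex=120)
        ref = make_reference_panel(cfg)
        track = simulate_depth(ref.targets, cfg, plex=1)
        loci = extract_low_coverage_loci(track, ref.targets, threshold=15)
        total = sum(l.length_bp for l in loci)
        exon1 = sum(l.length_bp for l in loci if l.exon_index == 1)
        assert total > 0 and exon1 / total >= 0.8

    def test_depth_determinism(self):
        cfg = SimulationConfig(seed=13, n_genes=3)
        ref = make_reference_panel(cfg)
        a = simulate_depth(ref.targets, cfg, plex=1)
        b = simulate_depth(ref.targets, cfg, plex=1)
        assert list(a.records()) == list(b.records())


class TestReplicates:
    def test_zero_noise_gives_perfect_pairwise_ogc(self):
        cfg = SimulationConfig(seed=14, replicate_noise=0.0, **SMALL)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        reps = simulate_replicates(truth, cfg)
        grid = pairwise_metrics(reps, ref.index)
        assert all(e.metrics.ogc == 1.0 for e in grid)

    def test_three_replicates_six_pairs_multiple_groupings(self):
        cfg = SimulationConfig(seed=15, n_replicates=3, **SMALL)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        reps = simulate_replicates(truth, cfg)
        grid = pairwise_metrics(reps, ref.index)
        assert len(grid) == 6
        groupings = set().union(*(e.groupings for e in grid))
        assert {"intra_run", "inter_run"} <= groupings

    def test_label_design_covers_all_factor_groupings(self):
        cfg = SimulationConfig(seed=16, n_replicates=4, **SMALL)
        ref = make_reference_panel(cfg)
        truth = simulate_truth(ref.targets, cfg)
        reps = simulate_replicates(truth, cfg)
        tags = set()
        for i, (a, _) in enumerate(reps):
            for b, _ in reps[i + 1:]:
                tags |= classify_pair(a, b)
        assert {"intra_run", "inter_run", "inter_operator", "inter_lot",
                "inter_day"} <= tags
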