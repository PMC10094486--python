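"""Ground-truth generator: panels, mosaics, counts, determinism."""

import numpy as np
import pandas as pd
import pytest

from polyhex.dosage import DosageModel
from polyhex.simulate import (
    SimConfig,
    TruthIndividual,
    build_parent_panel,
    draw_mosaic,
    emit_counts,
    load_truth,
    simulate_population,
    write_truth,
)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="p_chrom_gain"):
            SimConfig(p_chrom_gain=1.5).validate()

    def test_epsilon_separability_bound(self):
        with pytest.raises(ValueError, match="error_rate"):
            SimConfig(error_rate=0.3).validate()

    def test_short_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="5 Mb"):
            SimConfig(chrom_length_bp=1_000_000).validate()

    def test_intensity_shape_checked(self):
        with pytest.raises(ValueError, match="he_intensity"):
            SimConfig(he_intensity=np.ones(5)).validate()


class TestBuildParentPanel:
    def test_zero_snp_chromosome_errors_with_name(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_bp=5_000_000, snp_density=0.0)
        with pytest.raises(ValueError, match="Chr01"):
            build_parent_panel(cfg, np.random.default_rng(0))

    def test_deterministic_under_seed(self, small_cfg):
        p1 = build_parent_panel(small_cfg, np.random.default_rng(small_cfg.seed))
        p2 = build_parent_panel(small_cfg, np.random.default_rng(small_cfg.seed))
        pd.testing.assert_frame_equal(p1.snp, p2.snp)
        pd.testing.assert_frame_equal(p1.te_table, p2.te_table)
        pd.testing.assert_frame_equal(p1.genetic_map, p2.genetic_map)

    def test_snp_count_poisson_scale(self):
        # 12 x 30 Mb at 2 SNPs/kbp: mean 720,000, check within 3 SD
        cfg = SimConfig(snp_density=2.0, seed=1)
        panel = build_parent_panel(cfg, np.random.default_rng(cfg.seed))
        mean = 720_000
        assert abs(len(panel.snp) - mean) < 3 * np.sqrt(mean) + 12  # + unique() collisions

    def test_positions_strictly_increasing(self, small_panel):
        for _, grp in small_panel.snp.groupby("chrom", observed=True):
            assert grp["pos"].is_monotonic_increasing
            assert not grp["pos"].duplicated().any()

    def test_genetic_map_monotone_with_central_suppression(self, small_panel, small_cfg):
        for _, grp in small_panel.genetic_map.groupby("chrom", observed=True):
            assert grp["cM"].is_monotonic_increasing
            mid = small_cfg.chrom_length_bp / 2
            central = grp[np.abs(grp["pos_bp"] - mid) < 0.1 * mid]
            distal = grp[np.abs(grp["pos_bp"] - mid) > 0.8 * mid]
            rate = lambda g: np.ptp(g["cM"]) / np.ptp(g["pos_bp"])
            assert rate(central) < rate(distal)

    def test_te_classes_spatially_structured(self, small_panel, small_cfg):
        """Retrotransposons central, MITEs distal (radial density contrast)."""
        L = small_cfg.chrom_length_bp
        tes = small_panel.tes
        t = np.abs((tes["start"] + tes["end"]) / 2 - L / 2) / (L / 2)
        by_cls = t.groupby(tes["class"]).mean()
        assert by_cls["retrotransposon"] < by_cls["MITE"]


class TestDrawMosaic:
    def test_no_he_single_balanced_segment(self, small_cfg, small_panel, rng):
        cfg = SimConfig(**{**vars(small_cfg), "mean_he_per_chrom": 0.0})
        ind = draw_mosaic(cfg, small_panel, rng)
        for chrom in cfg.chrom_names:
            assert ind.segments[chrom] == [(0, cfg.chrom_length_bp, 2)]

    def test_segments_tile_and_adjacent_differ(self, small_cfg, small_panel, rng):
        cfg = SimConfig(**{**vars(small_cfg), "mean_he_per_chrom": 6.0})
        ind = draw_mosaic(cfg, small_panel, rng)
        for chrom in cfg.chrom_names:
            segs = ind.segments[chrom]
            assert segs[0][0] == 0 and segs[-1][1] == cfg.chrom_length_bp
            for (s1, e1, d1), (s2, e2, d2) in zip(segs, segs[1:]):
                assert e1 == s2
                assert abs(d2 - d1) == 1  # single-crossover step
                assert 0 <= d1 <= 4 and 0 <= d2 <= 4

    def test_intensity_concentrates_breakpoints(self, small_cfg, small_panel, rng):
        intensity = np.zeros(small_cfg.n_windows)
        intensity[3] = 1.0
        cfg = SimConfig(**{**vars(small_cfg), "he_intensity": intensity,
                           "mean_he_per_chrom": 4.0})
        ind = draw_mosaic(cfg, small_panel, rng)
        for chrom in cfg.chrom_names:
            for bp in ind.breakpoints(chrom):
                assert 3_000_000 <= bp < 4_000_000

    def test_all_zero_intensity_warns_and_falls_back_uniform(self, small_cfg, small_panel, rng):
        cfg = SimConfig(**{**vars(small_cfg), "he_intensity": np.zeros(small_cfg.n_windows),
                           "mean_he_per_chrom": 3.0})
        with pytest.warns(UserWarning, match="uniform"):
            draw_mosaic(cfg, small_panel, rng)

    def test_breakpoint_rate_matches_poisson_mean(self, small_panel):
        cfg = SimConfig(n_chromosomes=3, chrom_length_bp=8_000_000,
                        mean_he_per_chrom=3.0, seed=7)
        rng = np.random.default_rng(cfg.seed)
        n = 1000
        counts = [
            len(draw_mosaic(cfg, small_panel, rng, name=str(i)).breakpoints(chrom))
            for i in range(n)
            for chrom in cfg.chrom_names
        ]
        se = np.sqrt(3.0 / len(counts))
        assert abs(np.mean(counts) - 3.0) < 3 * se + 0.01  # + unique() collision slack


class TestEmitCounts:
    @staticmethod
    def uniform_truth(cfg, dosage):
        ind = TruthIndividual(name="t", generation="S2")
        for chrom in cfg.chrom_names:
            ind.segments[chrom] = [(0, cfg.chrom_length_bp, dosage)]
            ind.chrom_offset[chrom] = 0
            ind.offset_parent[chrom] = "9311"
            ind.seg_events[chrom] = []
        return ind

    def test_no_error_pure_dosage_all_reads_one_parent(self, small_cfg, small_panel, rng):
        cfg = SimConfig(**{**vars(small_cfg), "error_rate": 0.0})
        counts = emit_counts(self.uniform_truth(cfg, 4), small_panel, cfg, rng)
        assert (counts["count_nip"] == 0).all()

    def test_balanced_dosage_pooled_fraction(self, small_cfg, small_panel, rng):
        counts = emit_counts(self.uniform_truth(small_cfg, 2), small_panel, small_cfg, rng)
        a = counts["count_9311"].sum()
        n = a + counts["count_nip"].sum()
        se = 0.5 / np.sqrt(n)
        assert abs(a / n - 0.5) < 3 * se

    def test_chromosome_gain_shifts_depth_and_ratio(self, small_cfg, small_panel, rng):
        truth = self.uniform_truth(small_cfg, 2)
        truth.chrom_offset["Chr01"] = 1
        truth.offset_parent["Chr01"] = "9311"
        counts = emit_counts(truth, small_panel, small_cfg, rng)
        c1 = counts[counts["chrom"] == "Chr01"]
        rest = counts[counts["chrom"] != "Chr01"]
        depth1 = (c1["count_9311"] + c1["count_nip"]).mean()
        rest_depth = (rest["count_9311"] + rest["count_nip"]).mean()
        se = np.sqrt(small_cfg.per_site_depth * 1.25 / len(c1))
        assert abs(depth1 - 1.25 * small_cfg.per_site_depth) < 3 * se
        assert abs(rest_depth - small_cfg.per_site_depth) < 3 * se
        # 3 of 5 copies are 9311
        frac = c1["count_9311"].sum() / (c1["count_9311"] + c1["count_nip"]).sum()
        assert abs(frac - 0.6) < 0.01

    def test_site_depth_mean_within_one_percent(self, small_cfg, small_panel, rng):
        counts = emit_counts(self.uniform_truth(small_cfg, 2), small_panel, small_cfg, rng)
        assert len(counts) >= 1e4
        mean = (counts["count_9311"] + counts["count_nip"]).mean()
        assert abs(mean / small_cfg.per_site_depth - 1) < 0.01

    def test_infinite_depth_round_trip_recovers_truth(self, small_cfg, small_panel, rng):
        """Expectation-valued counts with eps=0 genotype back to the truth."""
        cfg = SimConfig(**{**vars(small_cfg), "error_rate": 0.0,
                           "mean_he_per_chrom": 2.0, "per_site_depth": 40.0})
        truth = draw_mosaic(cfg, small_panel, np.random.default_rng(99), name="rt")
        counts = emit_counts(truth, small_panel, cfg, rng, expected=True)
        res = DosageModel(counts, epsilon=0.005).fit()
        # every genotyped bin matches the truth dosage at its midpoint
        for _, row in res.bins.iterrows():
            if row["dosage"] < 0:
                continue
            mid = (row["start_pos"] + row["end_pos"]) / 2
            segs = truth.segments[row["chrom"]]
            true_d = next(d for s, e, d in segs if s <= mid - 1 < e)
            # bins straddling a breakpoint may genotype either flank
            flank_ok = any(
                abs(b - mid) < (row["end_pos"] - row["start_pos"])
                for b in truth.breakpoints(row["chrom"])
            )
            assert row["dosage"] == true_d or flank_ok


class TestPopulationAndTruthIO:
    def test_population_deterministic(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_bp=6_000_000,
                        n_individuals=2, seed=5)
        _, t1, c1 = simulate_population(cfg)
        _, t2, c2 = simulate_population(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        assert [t.segments for t in t1] == [t.segments for t in t2]

    def test_truth_json_round_trip(self, tmp_path, small_cfg, small_panel, rng):
        truth = draw_mosaic(small_cfg, small_panel, rng, name="x")
        path = tmp_path / "truth.json"
        write_truth([truth], path)
        back = load_truth(path)[0]
        assert back.segments == truth.segments
        assert back.chrom_offset == truth.chrom_offset
        assert back.euploid == truth.euploid
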