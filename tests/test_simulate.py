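import numpy as np
import pandas as pd
import pytest

from cnascanner.simulate import (
    SimConfig,
    SimTruth,
    make_size_grid,
    place_truth_intervals,
    run_sdx_experiment,
    simulate_cell,
    simulate_cohort,
    simulate_haplotype_depth,
)


class TestSizeGrid:
    def test_default_ladder(self):
        grid = make_size_grid()
        assert len(grid) == 13
        assert grid[0] == pytest.approx(200_000)
        assert grid[-1] == pytest.approx(5_000_000)

    def test_geometric_midpoint(self):
        # index 6 of 0..12 is the geometric mean sqrt(2e5 * 5e6) = 1 Mb
        assert make_size_grid()[6] == pytest.approx(1_000_000, rel=1e-9)

    def test_constant_ratio(self):
        grid = make_size_grid()
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            make_size_grid(5_000_000, 200_000)


def _quiet_config(**kw):
    defaults = dict(
        genome_length=10_000_000,
        poisson_noise=False,
        ado_rate_per_mb=0.0,
        gc_bias_amplitude=0.0,
        phase_switch_prob=0.0,
        exclusion_margin=1_000_000,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestHaplotypeDepth:
    def test_noise_free_track_is_flat(self):
        cfg = _quiet_config()
        track = simulate_haplotype_depth(cfg, "A", seed=1)
        np.testing.assert_allclose(track.rate, cfg.reads_per_bin_haploid)
        assert len(track.ado_intervals) == 0

    def test_ado_event_count_poisson(self):
        cfg = SimConfig(genome_length=100_000_000, ado_rate_per_mb=20.0, seed=0)
        track = simulate_haplotype_depth(cfg, "A", seed=123)
        expected = 20.0 * 100
        assert abs(len(track.ado_intervals) - expected) < 3 * np.sqrt(expected)

    def test_seed_reproducibility(self):
        cfg = SimConfig(genome_length=20_000_000)
        a = simulate_haplotype_depth(cfg, "A", seed=9)
        b = simulate_haplotype_depth(cfg, "A", seed=9)
        np.testing.assert_array_equal(a.rate, b.rate)
        np.testing.assert_array_equal(a.ado_intervals, b.ado_intervals)


class TestSpikeCna:
    @pytest.mark.parametrize(
        "cna_type,ratio",
        [("loss_1_0", 0.5), ("gain_2_1", 1.5), ("gain_3_1", 2.0), ("cnloh_2_0", 1.0)],
    )
    def test_depth_ratio_inside_event(self, cna_type, ratio):
        cfg = SimConfig(seed=5, genome_length=30_000_000)
        cell = simulate_cell(cfg, [(cna_type, 4_000_000)], seed=17)
        t = cell["truth"].iloc[0]
        obs = cell["observed"].astype(float)
        b0 = t.start // cfg.bin_size + 1
        b1 = t.end // cfg.bin_size - 1
        inside = obs[b0:b1].mean()
        flank = np.median(np.delete(obs, np.arange(b0 - 1, b1 + 1)))
        tol = 0.1 if cna_type != "cnloh_2_0" else 0.05
        assert inside / flank == pytest.approx(ratio, rel=tol)

    def test_cnloh_depth_conserved_exactly(self):
        """cnLOH spiking leaves binned total depth bitwise unchanged."""
        cfg = _quiet_config(genome_length=20_000_000)
        with_event = simulate_cell(cfg, [("cnloh_2_0", 3_000_000)], seed=3)
        without = simulate_cell(cfg, [], seed=3)
        np.testing.assert_array_equal(with_event["observed"], without["observed"])

    def test_cnloh_zeroes_b_allele_at_ghets(self):
        cfg = _quiet_config(genome_length=20_000_000)
        cell = simulate_cell(cfg, [("cnloh_2_0", 3_000_000)], seed=3)
        t = cell["truth"].iloc[0]
        snps = cell["snps"]
        inside = (snps["pos"] - 1 >= t.start) & (snps["pos"] - 1 < t.end)
        assert (snps.loc[inside, "depth_b"] == 0).all()
        # total site depth preserved: A carries both copies
        assert snps.loc[inside, "depth_a"].mean() == pytest.approx(
            2 * snps.loc[~inside, "depth_a"].mean(), rel=0.02
        )


class TestTruthPlacement:
    def test_non_overlapping_and_inside_margins(self, rng):
        cfg = SimConfig(genome_length=100_000_000, seed=0)
        truths = place_truth_intervals(
            cfg, [("loss_1_0", 2_000_000)] * 10, rng, min_gap=500_000
        )
        for t in truths:
            assert t.start >= cfg.exclusion_margin
            assert t.end <= cfg.genome_length - cfg.exclusion_margin
        for a, b in zip(truths, truths[1:]):
            assert a.end < b.start

    def test_oversized_event_rejected(self, rng):
        cfg = SimConfig(genome_length=10_000_000)
        with pytest.raises(ValueError):
            place_truth_intervals(cfg, [("loss_1_0", 9_000_000)], rng)

    def test_truth_type_validation(self):
        with pytest.raises(ValueError):
            SimTruth("not_a_type", "chrS", 0, 100)


class TestGhets:
    def test_density_five_per_10kb(self):
        cfg = _quiet_config(genome_length=5_000_000)
        cell = simulate_cell(cfg, [], seed=2)
        assert len(cell["snps"]) == 5 * (5_000_000 // 10_000)

    def test_phase_flip_fraction_binomial_band(self):
        cfg = SimConfig(genome_length=200_000_000, seed=4)
        cell = simulate_cell(cfg, [], seed=4)
        frac = cell["snps"]["phase_flipped"].mean()
        n = len(cell["snps"])
        assert n == 100_000
        assert abs(frac - 0.01) <= 3 * np.sqrt(0.01 * 0.99 / n)

    def test_diploid_baf_centered(self):
        """Marginal gHET BAF over diploid regions is centred at 0.5."""
        cfg = SimConfig(genome_length=150_000_000, seed=8)
        cell = simulate_cell(cfg, [], seed=8)
        snps = cell["snps"]
        tot = snps["depth_a"] + snps["depth_b"]
        baf = snps.loc[tot > 0, "depth_b"] / tot[tot > 0]
        assert len(snps) == 75_000
        assert abs(baf.mean() - 0.5) < 0.005


class TestExperimentDriver:
    def test_deterministic_truth(self, tmp_path):
        cfg = SimConfig(seed=77, genome_length=30_000_000)
        conds = [("loss_1_0", 1_000_000)]
        for sub in ("a", "b"):
            run_sdx_experiment(
                cfg, conditions=conds, out_dir=tmp_path / sub,
                cells_per_condition=3, write_cell_tables=False,
            )
        assert (tmp_path / "a/truth.bed").read_bytes() == (tmp_path / "b/truth.bed").read_bytes()

    def test_zero_plan_gives_empty_truth(self):
        cfg = SimConfig(seed=1, genome_length=20_000_000)
        bundle = simulate_cohort(cfg, {"only": []})
        assert bundle["truth"].empty
        assert set(bundle["cells"]) == {"only", "control"}

    def test_condition_emits_one_event_per_cell(self):
        cfg = SimConfig(seed=5, genome_length=30_000_000)
        out = run_sdx_experiment(
            cfg, conditions=[("gain_2_1", 500_000)], cells_per_condition=4,
        )
        assert len(out["truth"]) == 4
        assert (out["truth"]["cna_type"] == "gain_2_1").all()
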