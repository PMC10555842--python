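"""Synthetic lobule generator: determinism, geometry and emulated structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hepazone as hz
from hepazone.config import SimulatorConfig
from hepazone.simulate import ZonationProfile, profile_value, simulate_lobule
from hepazone.zonation import assign_bins, zonation_anova


class TestProfileValue:
    def test_flat_returns_baseline(self):
        prof = ZonationProfile("P", "flat", baseline=10.0)
        for r in (0.0, 0.3, 1.0):
            assert profile_value(prof, r) == 10.0

    def test_hockey_hand_evaluation(self):
        prof = ZonationProfile("P", "hockey_central", baseline=10.0,
                               amplitude=4.0, breakpoint=0.5, gamma=1.0)
        assert profile_value(prof, 0.75) == pytest.approx(12.0)

    def test_hockey_flat_before_breakpoint(self):
        prof = ZonationProfile("P", "hockey_central", baseline=10.0,
                               amplitude=4.0, breakpoint=0.5, gamma=2.0)
        for r in (0.0, 0.25, 0.5):
            assert profile_value(prof, r) == 10.0

    def test_hockey_portal_mirrors_central(self):
        central = ZonationProfile("P", "hockey_central", 10.0, 4.0, 0.4, 1.5)
        portal = ZonationProfile("P", "hockey_portal", 10.0, 4.0, 0.4, 1.5)
        r = np.linspace(0, 1, 11)
        np.testing.assert_allclose(profile_value(portal, r),
                                   profile_value(central, 1.0 - r))

    def test_linear_shapes(self):
        up = ZonationProfile("P", "linear_up", 10.0, 2.0)
        down = ZonationProfile("P", "linear_down", 10.0, 2.0)
        assert profile_value(up, 0.5) == 11.0
        assert profile_value(down, 0.0) == 12.0

    def test_out_of_range_rejected(self):
        prof = ZonationProfile("P", "flat", 10.0)
        with pytest.raises(ValueError):
            profile_value(prof, 1.5)

    def test_flat_with_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ZonationProfile("P", "flat", 10.0, amplitude=1.0)


class TestSimulateLobule:
    def test_seed_determinism(self):
        a = simulate_lobule(100, seed=7)
        b = simulate_lobule(100, seed=7)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        assert a.profiles == b.profiles

    def test_cardinality(self):
        assert len(simulate_lobule(100, seed=0).cells) == 100

    def test_r_true_uniform_between_landmarks(self):
        sim = SimulatorConfig(transverse_jitter_um=0.0)
        truth = simulate_lobule(2000, sim, seed=13)
        ks = stats.kstest(truth.cells["r_true"], "uniform").statistic
        assert ks < 0.05

    def test_r_consistent_with_landmark_distances(self):
        truth = simulate_lobule(50, seed=2)
        cells = truth.cells
        expected = cells["d_pv"] / (cells["d_pv"] + cells["d_cv"])
        np.testing.assert_allclose(cells["r_true"], expected, atol=1e-12)

    def test_areas_within_gates(self):
        sim = SimulatorConfig()
        truth = simulate_lobule(500, sim, seed=4)
        areas = truth.cells["area_um2"]
        assert (areas >= sim.area_min_um2).all()
        assert (areas <= sim.area_max_um2).all()
        assert np.median(areas) == pytest.approx(sim.area_log_median_um2, rel=0.15)

    def test_anucleate_point_mass(self):
        sim = SimulatorConfig(anucleate_fraction=0.25)
        truth = simulate_lobule(2000, sim, seed=5)
        frac0 = (truth.cells["nuclear_fraction"] == 0).mean()
        assert 0.2 < frac0 < 0.3

    def test_nonpositive_n_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_lobule(0, seed=1)

    def test_classes_are_r_quantile_segments(self):
        sim = SimulatorConfig(n_classes=5)
        truth = simulate_lobule(300, sim, seed=6)
        cells = truth.cells
        for k in range(1, 6):
            members = cells[cells["class_true"] == k]
            assert (members["r_true"] >= (k - 1) / 5 - 1e-12).all()
            assert (members["r_true"] <= k / 5 + 1e-12).all()


class TestSimulateProteome:
    def test_degenerate_noise_flat_protein_constant(self):
        sim = SimulatorConfig(n_proteins=10, zonated_fraction=0.0, n_histones=0,
                              noise_sd=0.0, missingness=False, area_coef=0.0)
        truth = simulate_lobule(20, sim, seed=8)
        matrix = hz.simulate_proteome(truth, sim)
        assert (matrix.nunique(axis=1) == 1).all()

    def test_histone_nuclear_coupling_linear(self):
        sim = SimulatorConfig(noise_sd=0.0, missingness=False, area_coef=0.0,
                              anucleate_fraction=0.0, histone_coef=2.0)
        truth = simulate_lobule(50, sim, seed=9)
        matrix = hz.simulate_proteome(truth, sim)
        hist = truth.histone_ids[0]
        nuc = truth.cells["nuclear_fraction"]
        slope = np.polyfit(nuc, matrix.loc[hist], 1)[0]
        assert slope == pytest.approx(2.0, abs=1e-9)

    def test_protein_count_tracks_log_area(self):
        sim = SimulatorConfig()
        truth = simulate_lobule(1000, sim, seed=10)
        matrix = hz.simulate_proteome(truth, sim)
        counts = matrix.notna().sum(axis=0)
        rho = stats.spearmanr(counts, np.log(truth.cells["area_um2"]))[0]
        assert rho > 0.5

    def test_completeness_increases_with_intensity(self):
        sim = SimulatorConfig()
        truth = simulate_lobule(400, sim, seed=11)
        matrix = hz.simulate_proteome(truth, sim)
        completeness = matrix.notna().mean(axis=1)
        median_intensity = matrix.median(axis=1)
        rho = stats.spearmanr(completeness, median_intensity)[0]
        assert rho > 0.5

    def test_negative_noise_rejected(self):
        truth = simulate_lobule(5, seed=1)
        with pytest.raises(ValueError):
            hz.simulate_proteome(truth, noise_sd=-1.0)

    def test_amplitude_monotone_in_anova_f(self):
        # doubling the hockey amplitude raises the ANOVA F statistic
        f_stats = []
        for amp in (1.0, 4.0):
            sim = SimulatorConfig(n_proteins=1, zonated_fraction=1.0, n_histones=0,
                                  amplitude_low=amp, amplitude_high=amp,
                                  missingness=False)
            truth = simulate_lobule(200, sim, seed=14)
            matrix = hz.simulate_proteome(truth, sim)
            bins = assign_bins(truth.cells["r_true"].to_numpy(), 20)
            res = zonation_anova(matrix, bins, 0.0, moderate=False)
            f_stats.append(res["F"].iloc[0])
        assert f_stats[1] > f_stats[0]


class TestSimulateReport:
    def test_noise_free_single_fragment_exact_ratio(self, clean_sim):
        cfg = clean_sim
        truth = simulate_lobule(cfg.n_cells, cfg, seed=3)
        matrix = hz.simulate_proteome(truth, cfg)
        report = hz.simulate_report(matrix, truth, cfg, frag_per_precursor=1)
        ref = report[report["Channel"] == 0].set_index(["Run", "Precursor.Id"])
        targets = report[report["Channel"] != 0]
        merged = targets.merge(
            truth.ratios, left_on=["Run", "Precursor.Id", "Channel"],
            right_on=["run", "precursor_id", "channel"],
        )
        for _, row in merged.head(20).iterrows():
            ref_frag = float(ref.loc[(row["Run"], row["Precursor.Id"]), "Fragment.Quant.Raw"])
            t_frag = float(row["Fragment.Quant.Raw"])
            assert t_frag / ref_frag == pytest.approx(row["ratio"], rel=1e-12)

    def test_three_channels_per_run(self, clean_sim):
        truth = simulate_lobule(clean_sim.n_cells, clean_sim, seed=3)
        matrix = hz.simulate_proteome(truth, clean_sim)
        report = hz.simulate_report(matrix, truth, clean_sim)
        channels_per_run = report.groupby("Run")["Channel"].agg(lambda c: set(c))
        assert all(chs == {0, 4, 8} for chs in channels_per_run)

    def test_q_fail_fractions_realized(self):
        sim = SimulatorConfig(n_cells=40, n_proteins=40,
                              q_fail_lib=0.1, q_fail_q=0.1, q_fail_channel=0.2)
        truth = simulate_lobule(sim.n_cells, sim, seed=15)
        matrix = hz.simulate_proteome(truth, sim)
        report = hz.simulate_report(matrix, truth, sim)
        assert (report["Lib.PG.Q.Value"] >= 0.01).mean() == pytest.approx(0.1, abs=0.02)
        assert (report["Channel.Q.Value"] >= 0.15).mean() == pytest.approx(0.2, abs=0.02)

    def test_seed_determinism(self, clean_sim):
        truth = simulate_lobule(clean_sim.n_cells, clean_sim, seed=3)
        matrix = hz.simulate_proteome(truth, clean_sim)
        r1 = hz.simulate_report(matrix, truth, clean_sim, seed=42)
        r2 = hz.simulate_report(matrix, truth, clean_sim, seed=42)
        pd.testing.assert_frame_equal(r1, r2)


class TestSimulateImages:
    def test_marker_channels_monotone_noise_free(self):
        sim = SimulatorConfig(pixel_noise_sd=0.0)
        truth = simulate_lobule(2, sim, seed=16)
        truth.cells.loc[:, "r_true"] = [0.05, 0.95]
        patches = hz.simulate_images(truth, sim)
        portal, central = list(patches.values())
        assert portal[2].mean() > central[2].mean()  # E-cadherin, 568
        assert central[3].mean() > portal[3].mean()  # Glul, 647

    def test_seed_determinism(self):
        sim = SimulatorConfig()
        truth = simulate_lobule(5, sim, seed=17)
        p1 = hz.simulate_images(truth, sim, seed=99)
        p2 = hz.simulate_images(truth, sim, seed=99)
        for cid in p1:
            np.testing.assert_array_equal(p1[cid], p2[cid])

    def test_ch647_tracks_r(self):
        sim = SimulatorConfig()
        truth = simulate_lobule(500, sim, seed=18)
        patches = hz.simulate_images(truth, sim)
        mean647 = [patches[c][3].mean() for c in truth.cells.index]
        rho = stats.spearmanr(mean647, truth.cells["r_true"])[0]
        assert rho > 0.8

    def test_pixels_nonnegative_and_patch_size(self):
        sim = SimulatorConfig(pixel_noise_sd=200.0, patch_size=6)
        truth = simulate_lobule(10, sim, seed=19)
        patches = hz.simulate_images(truth, sim)
        for patch in patches.values():
            assert patch.shape == (4, 6, 6)
            assert (patch >= 0).all()

    def test_small_patch_rejected(self):
        truth = simulate_lobule(2, seed=20)
        with pytest.raises(ValueError):
            hz.simulate_images(truth, patch_size=2)
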