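"""Axis mapping, binning, zonation ANOVA and spatial profile summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hepazone import zonation
from hepazone.zonation import (
    annotation_proportions,
    assign_bins,
    bin_profile,
    center_log2fc,
    flatness_test,
    pca,
    pseudo_neighbors,
    relative_distance,
    zonation_anova,
)


class TestRelativeDistance:
    def test_at_portal_vein(self):
        assert relative_distance(0.0, 80.0) == 0.0

    def test_symmetry_midpoint(self):
        assert relative_distance(25.0, 25.0) == 0.5

    def test_arithmetic(self):
        assert relative_distance(30.0, 10.0) == pytest.approx(0.75)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_distance(0.0, 0.0)


class TestAssignBins:
    def test_edges(self):
        bins = assign_bins([0.0, 1.0], 20)
        assert list(bins) == [1, 20]

    def test_midpoint(self):
        assert assign_bins([0.5], 20)[0] == 11

    def test_nine_bin_rebinning(self):
        # generic bin count supports the cross-omics nine-bin layout
        r = np.linspace(0, 1, 10)
        bins = assign_bins(r, 9)
        assert bins.min() == 1 and bins.max() == 9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_bins([1.2], 20)


class TestZonationAnova:
    def test_hand_anova_two_bins(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["P"])
        matrix.columns = [f"s{i}" for i in range(6)]
        bins = np.array([1, 1, 1, 2, 2, 2])
        res = zonation_anova(matrix, bins, completeness_min=0.0, moderate=False)
        assert res.loc["P", "F"] == pytest.approx(13.5)
        assert res.loc["P", "p"] == pytest.approx(0.0214, abs=2e-4)

    def test_constant_protein_null(self):
        matrix = pd.DataFrame([[5.0] * 8], index=["P"],
                              columns=[f"s{i}" for i in range(8)])
        bins = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        res = zonation_anova(matrix, bins, completeness_min=0.0, moderate=False)
        assert res.loc["P", "F"] == 0.0
        assert res.loc["P", "p"] == 1.0

    def test_permutation_null_calibration(self, rng):
        # plain ANOVA p-values on a null protein are uniform
        n = 40
        bins = np.repeat(np.arange(1, 5), 10)
        rejections = 0
        n_perm = 1000
        values = rng.normal(0, 1, n)
        matrix = pd.DataFrame([values], index=["P"],
                              columns=[f"s{i}" for i in range(n)])
        for _ in range(n_perm):
            perm = rng.permutation(n)
            res = zonation_anova(matrix, bins[perm], completeness_min=0.0, moderate=False)
            rejections += res.loc["P", "p"] < 0.05
        assert 0.03 <= rejections / n_perm <= 0.07

    def test_moderation_shrinks_variance_outliers(self, rng):
        # moderated F for a protein with tiny residual variance is damped
        n_prot, n = 200, 40
        bins = np.repeat(np.arange(1, 5), 10)
        X = rng.normal(10, 1, (n_prot, n))
        X[0] = 10.0 + rng.normal(0, 0.01, n)  # near-zero residual variance
        X[0, :10] += 0.05
        matrix = pd.DataFrame(X, index=[f"P{i}" for i in range(n_prot)],
                              columns=[f"s{i}" for i in range(n)])
        plain = zonation_anova(matrix, bins, 0.0, moderate=False)
        mod = zonation_anova(matrix, bins, 0.0, moderate=True)
        assert mod.loc["P0", "F"] < plain.loc["P0", "F"]

    def test_incomplete_protein_not_tested(self):
        matrix = pd.DataFrame([[1.0, np.nan, np.nan, np.nan, 2.0, np.nan]],
                              index=["P"], columns=[f"s{i}" for i in range(6)])
        bins = np.array([1, 1, 1, 2, 2, 2])
        res = zonation_anova(matrix, bins, completeness_min=0.5)
        assert not res.loc["P", "tested"]
        assert np.isnan(res.loc["P", "p"])

    def test_fdr_never_below_p(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 1, (50, 40)),
                              columns=[f"s{i}" for i in range(40)])
        bins = np.repeat(np.arange(1, 5), 10)
        res = zonation_anova(matrix, bins, 0.0, moderate=True)
        ok = res["tested"]
        assert (res.loc[ok, "fdr"] >= res.loc[ok, "p"] - 1e-12).all()


class TestFlatness:
    def test_gaussian_sample_is_flat(self, rng):
        matrix = pd.DataFrame([rng.normal(10, 1, 200)], index=["P"],
                              columns=[f"s{i}" for i in range(200)])
        res = flatness_test(matrix)
        assert res.loc["P", "flat"] == 1.0

    def test_bimodal_sample_is_not_flat(self, rng):
        values = np.concatenate([rng.normal(0, 1, 100), rng.normal(6, 1, 100)])
        matrix = pd.DataFrame([values], index=["P"],
                              columns=[f"s{i}" for i in range(200)])
        res = flatness_test(matrix)
        # sanity: an independent Shapiro-Wilk run agrees
        assert stats.shapiro(values).pvalue < 0.05
        assert res.loc["P", "flat"] == 0.0

    def test_adjusted_never_below_raw(self, rng):
        matrix = pd.DataFrame(rng.normal(0, 1, (20, 50)),
                              columns=[f"s{i}" for i in range(50)])
        res = flatness_test(matrix)
        ok = res["tested"]
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p"] - 1e-12).all()

    def test_too_few_observations_untested(self):
        matrix = pd.DataFrame([[1.0, 2.0, np.nan, np.nan]],
                              index=["P"], columns=list("abcd"))
        res = flatness_test(matrix)
        assert not res.loc["P", "tested"]


class TestBinProfile:
    def test_constant_protein_uniform(self):
        matrix = pd.DataFrame([[3.0] * 6], index=["P"],
                              columns=[f"s{i}" for i in range(6)])
        bins = np.array([1, 1, 2, 2, 3, 3])
        prof = bin_profile(matrix, bins)
        np.testing.assert_allclose(prof.loc["P"].to_numpy(), [1 / 3] * 3)

    def test_normalization_arithmetic(self):
        # linear bin means (1, 1, 2) -> (0.25, 0.25, 0.5)
        matrix = pd.DataFrame([np.log2([1.0, 1.0, 2.0])], index=["P"],
                              columns=list("abc"))
        prof = bin_profile(matrix, np.array([1, 2, 3]))
        np.testing.assert_allclose(prof.loc["P"].to_numpy(), [0.25, 0.25, 0.5])

    def test_scale_invariance_and_simplex(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 2, (5, 20)),
                              columns=[f"s{i}" for i in range(20)])
        bins = np.repeat(np.arange(1, 5), 5)
        p1 = bin_profile(matrix, bins)
        p2 = bin_profile(matrix + 3.0, bins)  # x8 on the linear scale
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(np.nansum(p1.to_numpy(), axis=1), 1.0, atol=1e-12)


class TestCenterLog2FC:
    def test_hand_arithmetic(self):
        # linear bin means (2, 2, 4, 8); centre pair (2, 4), median 3
        matrix = pd.DataFrame([np.log2([2.0, 2.0, 4.0, 8.0])], index=["P"],
                              columns=list("abcd"))
        out = center_log2fc(matrix, np.array([1, 2, 3, 4]))
        np.testing.assert_allclose(
            out.loc["P"].to_numpy(),
            [-0.585, -0.585, 0.415, 1.415], atol=5e-4,
        )

    def test_flat_protein_all_zero(self):
        matrix = pd.DataFrame([[7.0] * 4], index=["P"], columns=list("abcd"))
        out = center_log2fc(matrix, np.array([1, 2, 3, 4]))
        np.testing.assert_allclose(out.loc["P"].to_numpy(), 0.0, atol=1e-12)

    def test_log_shift_invariance(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 1, (3, 8)),
                              columns=[f"s{i}" for i in range(8)])
        bins = np.repeat(np.arange(1, 5), 2)
        out1 = center_log2fc(matrix, bins)
        out2 = center_log2fc(matrix + 5.0, bins)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-9)


class TestAnnotationProportions:
    def test_single_set_is_all_ones(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 1, (4, 6)),
                              index=list("wxyz"), columns=[f"s{i}" for i in range(6)])
        bins = np.array([1, 1, 2, 2, 3, 3])
        out = annotation_proportions(matrix, {"all": list("wxyz")}, bins)
        np.testing.assert_allclose(out.loc["all"].to_numpy(), 1.0)

    def test_three_to_one_split(self):
        matrix = pd.DataFrame(
            [np.log2([3.0, 3.0]), np.log2([1.0, 1.0])],
            index=["a", "b"], columns=["s1", "s2"],
        )
        out = annotation_proportions(matrix, {"A": ["a"], "B": ["b"]}, np.array([1, 1]))
        assert out.loc["A", "bin1"] == pytest.approx(0.75)
        assert out.loc["B", "bin1"] == pytest.approx(0.25)

    def test_simplex_per_bin_and_other_pool(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 1, (6, 9)),
                              index=list("abcdef"), columns=[f"s{i}" for i in range(9)])
        bins = np.repeat([1, 2, 3], 3)
        out = annotation_proportions(matrix, {"A": ["a", "b"]}, bins)
        assert "other" in out.index
        np.testing.assert_allclose(out.sum(axis=0).to_numpy(), 1.0, atol=1e-12)


class TestPseudoNeighbors:
    def test_k1_identity(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 1, (8, 6)),
                              columns=[f"s{i}" for i in range(6)])
        r = np.linspace(0, 1, 6)
        combined, curve = pseudo_neighbors(matrix, r, k=1, pca_completeness_min=0.0)
        np.testing.assert_allclose(combined.to_numpy(), matrix.to_numpy())
        assert curve.k == 1

    def test_pairwise_means(self):
        matrix = pd.DataFrame([[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 8.0, 8.0]],
                              index=["P", "Q"], columns=list("abcd"))
        r = np.array([0.1, 0.2, 0.8, 0.9])
        combined, _ = pseudo_neighbors(matrix, r, k=2, pca_completeness_min=0.0)
        np.testing.assert_allclose(combined.loc["P"].to_numpy(), [2.0, 6.0])
        np.testing.assert_allclose(combined.loc["Q"].to_numpy(), [2.0, 8.0])

    def test_grand_mean_conserved_when_k_divides_n(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 1, (5, 12)),
                              columns=[f"s{i}" for i in range(12)])
        r = rng.uniform(0, 1, 12)
        combined, _ = pseudo_neighbors(matrix, r, k=4, pca_completeness_min=0.0)
        np.testing.assert_allclose(
            combined.mean(axis=1).to_numpy(), matrix.mean(axis=1).to_numpy(), atol=1e-12
        )

    def test_k_too_large_rejected(self, rng):
        matrix = pd.DataFrame(rng.normal(10, 1, (5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            pseudo_neighbors(matrix, np.linspace(0, 1, 4), k=5)

    def test_pc1_gains_importance_on_zonated_data(self):
        import hepazone as hz
        from hepazone.config import SimulatorConfig

        sim = SimulatorConfig(missingness=False)
        truth = hz.simulate_lobule(400, sim, seed=9)
        matrix = hz.simulate_proteome(truth, sim)
        r = truth.cells["r_true"].to_numpy()
        fracs = []
        for k in (1, 2, 4):
            _, curve = pseudo_neighbors(matrix, r, k=k)
            fracs.append(curve.variance_fractions[0])
        assert fracs[0] <= fracs[1] <= fracs[2]


class TestPCA:
    def test_rank_one_from_correlated_proteins(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        matrix = pd.DataFrame([s, 2 * s + 1], index=["a", "b"], columns=list("wxyz"))
        result = pca(matrix, completeness_min=0.0)
        assert result.variance_fractions[0] == pytest.approx(1.0)

    def test_matches_direct_svd(self, rng):
        matrix = pd.DataFrame(rng.normal(0, 1, (3, 3)),
                              index=list("abc"), columns=list("xyz"))
        result = pca(matrix, completeness_min=0.0)
        X = matrix.to_numpy().T
        X = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        scores_ref = U * S
        for j in range(result.scores.shape[1]):
            ours = result.scores.iloc[:, j].to_numpy()
            ref = scores_ref[:, j]
            assert (np.allclose(ours, ref, atol=1e-9)
                    or np.allclose(ours, -ref, atol=1e-9))

    def test_sign_convention_deterministic(self, rng):
        matrix = pd.DataFrame(rng.normal(0, 1, (10, 8)),
                              columns=[f"s{i}" for i in range(8)])
        r1 = pca(matrix, completeness_min=0.0)
        r2 = pca(matrix.copy(), completeness_min=0.0)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        for j in range(r1.loadings.shape[1]):
            col = r1.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_matrix_rejected(self):
        matrix = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            pca(matrix, completeness_min=0.0)

    def test_pc1_tracks_axis_on_zonated_simulation(self):
        import hepazone as hz
        from hepazone.config import SimulatorConfig

        sim = SimulatorConfig()
        truth = hz.simulate_lobule(300, sim, seed=21)
        matrix = hz.simulate_proteome(truth, sim)
        result = pca(matrix, completeness_min=0.7)
        rho = stats.spearmanr(result.scores["PC1"],
                              truth.cells["r_true"].loc[result.scores.index])[0]
        assert abs(rho) > 0.9
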