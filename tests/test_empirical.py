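"""Tests for the expression-matrix pliancy analytics.

The tiny_matrix fixture (3 genes x 8 cells, hand-chosen integers) backs the
hand-computed oracles; the session synth_matrix backs the statistical
behavior checks.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pliancy as pl
from pliancy.empirical import (
    LabeledExpressionMatrix,
    centroid_distance,
    genewise_pliancy,
    logfold_sum_permutation,
    pliancy_zscore,
    positive_coeff_bootstrap,
    rank_sum_de,
    zscore_regression,
)
from pliancy.synth import SynthExprConfig, synth_expression


class TestContainer:
    def test_duplicate_genes_rejected(self, tiny_matrix):
        v = tiny_matrix.values.copy()
        v.index = ["g1", "g1", "g3"]
        with pytest.raises(ValueError, match="duplicate"):
            LabeledExpressionMatrix(v, tiny_matrix.cell_category,
                                    tiny_matrix.polycomb)

    def test_unlabeled_cell_rejected(self, tiny_matrix):
        cats = tiny_matrix.cell_category.drop("c3")
        with pytest.raises(ValueError, match="category"):
            LabeledExpressionMatrix(tiny_matrix.values, cats,
                                    tiny_matrix.polycomb)

    def test_nan_rejected(self, tiny_matrix):
        v = tiny_matrix.values.copy()
        v.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            LabeledExpressionMatrix(v, tiny_matrix.cell_category,
                                    tiny_matrix.polycomb)


class TestCentroidDistance:
    def test_identical_groups_zero(self, tiny_matrix):
        cells = list(tiny_matrix.cells_in("primary"))
        assert centroid_distance(tiny_matrix, cells, cells) == 0.0

    def test_single_gene_shift(self):
        genes = pd.Index(["g"])
        cells = pd.Index(["a1", "a2", "b1", "b2"])
        v = pd.DataFrame([[1.0, 1.0, 3.5, 3.5]], index=genes, columns=cells)
        m = LabeledExpressionMatrix(v, pd.Series(["primary"] * 2 +
                                                 ["metastatic"] * 2,
                                                 index=cells),
                                    pd.Series(False, index=genes))
        assert centroid_distance(m, "primary", "metastatic") == pytest.approx(2.5)

    def test_cell_permutation_invariance(self, synth_matrix, rng):
        d1 = centroid_distance(synth_matrix, "primary", "metastatic")
        cells = list(synth_matrix.cells_in("primary"))
        rng.shuffle(cells)
        d2 = centroid_distance(synth_matrix, cells, "metastatic")
        assert d1 == pytest.approx(d2)

    def test_empty_subset_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            centroid_distance(tiny_matrix, "primary", "metastatic",
                              gene_subset=[])


class TestGenewisePliancy:
    def test_hand_case(self, tiny_matrix):
        # g1: mu_p=1.5, mu_m=4, n_met=1.5, n_prim=0 -> |4-1.5|=2.5 > |1.5-0|=1.5: not pliant
        # g2: mu_p=4, mu_m ~1.33, n_met=5.5, n_prim=6 -> |1.33-5.5|=4.17 > |4-6|=2: not pliant
        # g3: all equal -> tie, not pliant
        flags, prop, p = genewise_pliancy(tiny_matrix)
        assert list(flags) == [False, False, False]
        assert prop == 0.0

    def test_metastatic_at_normal_is_fully_pliant(self, rng):
        genes = pd.Index([f"g{i}" for i in range(20)])
        cells = pd.Index([f"c{i}" for i in range(30)])
        cats = pd.Series(["primary"] * 10 + ["metastatic"] * 10 +
                         ["normal_primary_site"] * 10, index=cells)
        base = rng.normal(0, 1, (20, 1))
        v = np.tile(base, (1, 30))
        v[:, :10] += 2.0  # primary shifted away
        m = LabeledExpressionMatrix(pd.DataFrame(v, index=genes, columns=cells),
                                    cats, pd.Series(False, index=genes))
        _, prop, p = genewise_pliancy(m)
        assert prop == 1.0
        assert p < 1e-5

    def test_proportion_matches_generator_oracle(self):
        """At lam=0.8 the pliant proportion matches a Monte-Carlo expectation
        computed from independent draws of the same generator."""
        cfg = SynthExprConfig(seed=None, n_genes=2000)
        oracle = []
        for seed in range(5):
            m = synth_expression(SynthExprConfig(seed=100 + seed, n_genes=2000))
            _, prop, _ = genewise_pliancy(m)
            oracle.append(prop)
        m = synth_expression(SynthExprConfig(seed=1, n_genes=2000))
        _, prop, _ = genewise_pliancy(m)
        assert abs(prop - np.mean(oracle)) < 0.05


class TestPliancyZScore:
    def test_hand_computed_toy_case(self):
        """2 genes, 3 metastatic + 2 normal cells with small integer values;
        expected z_c derived by hand before implementation:

        gene A: met = (1, 2, 3), mu_m = 2, sd_m = sqrt(2/3); normal mu = 0,
                orient = +1 -> z' = (-1, 0, +1)/sqrt(2/3)
        gene B: met = (4, 4, 1), mu_m = 3, sd_m = sqrt(2); normal mu = 5,
                orient = -1 -> z' = -(1, 1, -2)/sqrt(2)
        z_c = mean over genes.
        """
        genes = pd.Index(["A", "B"])
        cells = pd.Index(["m1", "m2", "m3", "n1", "n2"])
        v = pd.DataFrame([[1.0, 2.0, 3.0, 0.0, 0.0],
                          [4.0, 4.0, 1.0, 5.0, 5.0]],
                         index=genes, columns=cells)
        m = LabeledExpressionMatrix(
            v, pd.Series(["metastatic"] * 3 + ["normal_met_site"] * 2,
                         index=cells),
            pd.Series(False, index=genes))
        res = pliancy_zscore(m)
        sa = np.sqrt(2.0 / 3.0)
        sb = np.sqrt(2.0)
        expect = [(-1 / sa - 1 / sb) / 2, (0 - 1 / sb) / 2, (1 / sa + 2 / sb) / 2]
        np.testing.assert_allclose(res.z.values, expect, atol=1e-12)

    def test_mean_zero_identity(self, synth_matrix):
        res = pliancy_zscore(
            synth_matrix,
            synth_matrix.gene_ids.difference(synth_matrix.polycomb_genes()))
        assert abs(res.z.mean()) < 1e-10

    def test_cell_at_centroid_scores_zero(self, rng):
        """A metastatic cell lying exactly on the metastatic centroid gets
        z_c = 0: build m1, m2 = mu +- d so that m3 = mu is the centroid."""
        genes = pd.Index(["a", "b", "c"])
        cells = pd.Index(["m1", "m2", "m3", "n1", "n2"])
        mu = rng.normal(0, 1, 3)
        d = rng.normal(1, 0.2, 3)
        met = np.column_stack([mu + d, mu - d, mu])
        v = pd.DataFrame(np.column_stack([met, rng.normal(0, 1, (3, 2))]),
                         index=genes, columns=cells)
        m = LabeledExpressionMatrix(
            v, pd.Series(["metastatic"] * 3 + ["normal_met_site"] * 2,
                         index=cells),
            pd.Series(False, index=genes))
        res = pliancy_zscore(m)
        assert res.z["m3"] == pytest.approx(0.0, abs=1e-12)

    def test_sign_coherence(self, synth_matrix):
        """Moving every metastatic cell toward the normal centroid decreases
        every cell's score when measured against the fixed gene statistics
        (negative = toward normal)."""
        genes = synth_matrix.gene_ids.difference(synth_matrix.polycomb_genes())
        base = pliancy_zscore(synth_matrix, genes)
        used = base.genes_used
        met = synth_matrix.cells_in("metastatic")
        x = synth_matrix.values.loc[used, met]
        target = base.mu_normal[used]
        shifted = x.add(0.3 * (target - x.T).T)
        orient = np.sign(base.mu_met[used] - base.mu_normal[used])
        z_shift = (shifted.sub(base.mu_met[used], axis=0)
                   .div(base.sigma_met[used], axis=0)
                   .mul(orient, axis=0).mean(axis=0))
        assert (z_shift < base.z - 1e-12).all()

    def test_polycomb_overlap_refused(self, synth_matrix):
        with pytest.raises(ValueError, match="polycomb"):
            pliancy_zscore(synth_matrix, synth_matrix.gene_ids)


class TestRegressionAndBootstrap:
    def test_single_perfect_predictor(self, rng):
        genes = pd.Index(["pc", "x1", "x2"])
        cells = pd.Index([f"m{i}" for i in range(20)] + ["n1", "n2"])
        z = rng.normal(0, 1, 20)
        v = pd.DataFrame(rng.normal(0, 1, (3, 22)), index=genes, columns=cells)
        v.loc["pc", cells[:20]] = z
        m = LabeledExpressionMatrix(
            v, pd.Series(["metastatic"] * 20 + ["normal_met_site"] * 2,
                         index=cells),
            pd.Series([True, False, False], index=genes))
        zs = pd.Series(z, index=cells[:20])
        coefs, r2, pos = zscore_regression(m, ["pc"], zscores=zs)
        assert coefs["pc"] == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert pos == 1

    def test_zero_response_convention(self, synth_matrix):
        met = synth_matrix.cells_in("metastatic")
        zs = pd.Series(0.0, index=met)
        coefs, r2, pos = zscore_regression(synth_matrix, zscores=zs)
        assert (coefs == 0).all() and r2 == 0.0 and pos == 0

    def test_too_few_cells_explicit_failure(self, rng):
        cfg = SynthExprConfig(seed=3, n_genes=100, n_metastatic=20,
                              n_polycomb=30)
        m = synth_expression(cfg)
        with pytest.raises(ValueError, match="predictors"):
            zscore_regression(m)

    def test_polycomb_effect_recovered(self, synth_matrix):
        """With beta>0 the designated genes' positive-coefficient count is
        significant against the random-gene bootstrap null."""
        rng = np.random.default_rng(5)
        obs, null, p = positive_coeff_bootstrap(synth_matrix, n_boot=200,
                                                rng=rng)
        assert obs > null.mean()
        assert p < 0.05

    def test_beta_zero_not_significant(self):
        rng = np.random.default_rng(6)
        m = synth_expression(SynthExprConfig(seed=9, beta=0.0))
        obs, null, p = positive_coeff_bootstrap(m, n_boot=200, rng=rng)
        assert p > 0.05

    def test_bootstrap_contract(self, synth_matrix):
        rng = np.random.default_rng(7)
        obs, null, p = positive_coeff_bootstrap(synth_matrix, n_boot=50,
                                                rng=rng)
        assert len(null) == 50
        assert 0 < p <= 1


class TestPermutationTest:
    def test_null_histogram_size_and_symmetric_p(self, synth_matrix, rng):
        obs, null, p = logfold_sum_permutation(synth_matrix, n_perm=199,
                                               rng=rng)
        assert len(null) == 199
        assert 0 < p <= 1

    def test_seeded_invariance_to_gene_and_cell_order(self, synth_matrix):
        m1 = synth_matrix
        perm_genes = m1.gene_ids[::-1]
        perm_cells = m1.cell_ids[::-1]
        m2 = LabeledExpressionMatrix(
            m1.values.loc[perm_genes, perm_cells],
            m1.cell_category[perm_cells], m1.polycomb[perm_genes])
        _, n1, p1 = logfold_sum_permutation(m1, n_perm=50,
                                            rng=np.random.default_rng(3))
        _, n2, p2 = logfold_sum_permutation(m2, n_perm=50,
                                            rng=np.random.default_rng(3))
        assert p1 == p2
        np.testing.assert_allclose(np.sort(n1), np.sort(n2), atol=1e-9)

    def test_uniform_under_exchangeable_null(self):
        """p-values are approximately uniform when primary and metastatic
        cells are exchangeable (smaller replicate of the calibration used in
        the acceptance suite)."""
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            m = synth_expression(SynthExprConfig(
                seed=2000 + seed, n_genes=40, n_primary=25, n_metastatic=25,
                n_normal_primary=10, n_normal_met=10, lam=0.0, beta=0.0,
                n_polycomb=20))
            _, _, p = logfold_sum_permutation(m, n_perm=99, rng=rng)
            ps.append(p)
        stat = stats.kstest(ps, "uniform").statistic
        assert stat < 0.2


class TestRankSumDE:
    def test_identical_groups_zero_lfc(self, tiny_matrix):
        cells = list(tiny_matrix.cells_in("metastatic"))
        df = rank_sum_de(tiny_matrix, cells, cells)
        assert (df["log_fold_change"] == 0).all()

    def test_bh_adjustment_dominates_raw(self, synth_matrix):
        df = rank_sum_de(synth_matrix, "primary", "metastatic")
        assert (df["padj"] >= df["pvalue"] - 1e-15).all()

    def test_statistic_matches_hand_ranked_case(self):
        """A = {1,2,3}, B = {4,5,6}: rank-sum statistic equals the value
        computed from the closed form for fully separated groups."""
        genes = pd.Index(["g"])
        cells = pd.Index(list("abcdef"))
        v = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=genes,
                         columns=cells)
        m = LabeledExpressionMatrix(
            v, pd.Series(["primary"] * 3 + ["metastatic"] * 3, index=cells),
            pd.Series(False, index=genes))
        df = rank_sum_de(m, "primary", "metastatic")
        # rank sum of A = 1+2+3 = 6; expectation 10.5, sd = sqrt(9*7/12)
        expect = (6 - 10.5) / np.sqrt(9 * 7 / 12.0)
        assert df["statistic"].iloc[0] == pytest.approx(expect)
        assert df["log_fold_change"].iloc[0] == pytest.approx(-3.0)


def test_operations_leave_input_unmodified(synth_matrix):
    before = synth_matrix.values.copy()
    genes = synth_matrix.gene_ids.difference(synth_matrix.polycomb_genes())
    pliancy_zscore(synth_matrix, genes)
    genewise_pliancy(synth_matrix)
    centroid_distance(synth_matrix, "primary", "metastatic")
    logfold_sum_permutation(synth_matrix, n_perm=5,
                            rng=np.random.default_rng(0))
    pd.testing.assert_frame_equal(synth_matrix.values, before)


def test_pca_projection_layout_and_separation(synth_matrix):
    """Projection returns one row per cell with its category, and the first
    components separate the primary and normal centroids."""
    from pliancy.empirical import pca_projection

    df = pca_projection(synth_matrix, n_components=2)
    assert list(df.columns) == ["PC1", "PC2", "category"]
    assert len(df) == len(synth_matrix.cell_ids)
    cent = df.groupby("category")[["PC1", "PC2"]].mean()
    gap = np.linalg.norm(cent.loc["primary"] - cent.loc["normal_primary_site"])
    within = df[df.category == "primary"][["PC1", "PC2"]].std().mean()
    assert gap > within
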