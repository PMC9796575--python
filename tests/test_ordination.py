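"""Unweighted UniFrac, PCoA, PERMANOVA and RDA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova

from porescreen.ordination import (
    RootedTree,
    factor_fit,
    pcoa,
    permanova,
    rda,
    unifrac_matrix,
    unweighted_unifrac,
)
from porescreen.simulate import simulate_tree


@pytest.fixture
def four_leaf_tree():
    return RootedTree(TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"]))


class TestUnweightedUnifrac:
    def test_identical_sets_zero(self, four_leaf_tree):
        assert unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"A", "B"}) == 0.0

    def test_disjoint_clades_distance_one(self, four_leaf_tree):
        assert unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"C", "D"}) == 1.0

    def test_partial_overlap_hand_value(self, four_leaf_tree):
        # unique branches B, C, CD-stem (3) over union A, B, AB-stem, C,
        # CD-stem (5)
        assert unweighted_unifrac(four_leaf_tree, {"A", "B"}, {"A", "C"}) == (
            pytest.approx(0.6)
        )

    def test_both_empty_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError):
            unweighted_unifrac(four_leaf_tree, set(), set())

    def test_missing_leaf_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError, match="absent"):
            unweighted_unifrac(four_leaf_tree, {"A"}, {"Z"})

    def test_matrix_symmetric_zero_diagonal(self, four_leaf_tree):
        presence = pd.DataFrame(
            np.array([[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 0, 1]], bool),
            index=["x", "y", "z"],
            columns=list("ABCD"),
        )
        d = unifrac_matrix(four_leaf_tree, presence)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_agrees_with_skbio_on_random_trees(self):
        """Independent cross-check: random coalescent trees and random
        presence patterns, compared against scikit-bio's implementation."""
        rng = np.random.default_rng(7)
        for seed in range(5):
            n = 12
            taxa = [f"OTU_{i:03d}" for i in range(n)]
            tree = simulate_tree(taxa, seed=seed)
            presence = rng.random((6, n)) < 0.5
            presence[:, 0] = True  # no empty samples
            counts = presence.astype(int)
            ref = beta_diversity(
                "unweighted_unifrac",
                counts,
                ids=[f"s{i}" for i in range(6)],
                taxa=taxa,
                tree=tree.tree,
            ).data
            ours = unifrac_matrix(
                tree,
                pd.DataFrame(
                    presence, index=[f"s{i}" for i in range(6)], columns=taxa
                ),
            ).to_numpy()
            assert np.allclose(ours, ref, atol=1e-12)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.0], [4.0]])
        D = squareform(pdist(pts))
        res = pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 1
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(recon, D, atol=1e-9)

    def test_euclidean_cloud_exact_recovery(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        res = pcoa(D, k=2)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(recon, D, atol=1e-9)
        assert (res.eigenvalues > -1e-9).all()

    def test_equilateral_triple_degenerate_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(D)
        ev = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(ev) == 2 and ev[0] == pytest.approx(ev[1])

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        res = pcoa(D)
        n = D.shape[0]
        A = -0.5 * D**2
        J = np.eye(n) - np.ones((n, n)) / n
        assert res.eigenvalues.sum() == pytest.approx(np.trace(J @ A @ J), abs=1e-9)

    def test_excess_axes_truncated_with_warning(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning, match="truncating"):
            res = pcoa(D, k=5)
        assert res.coordinates.shape[1] == 2

    def test_matches_skbio_coordinates(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        D = squareform(pdist(pts))
        ours = pcoa(D, k=3).coordinates.to_numpy()
        import skbio.stats.ordination as sko

        ref = sko.pcoa(SkbioDM(D), number_of_dimensions=3).samples.to_numpy()
        for j in range(3):  # axes defined up to sign
            assert np.allclose(ours[:, j], ref[:, j], atol=1e-8) or np.allclose(
                ours[:, j], -ref[:, j], atol=1e-8
            )


def _two_clouds(sep, n=10, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, 2))
    b = rng.normal(size=(n, 2)) + sep
    pts = np.vstack([a, b])
    return squareform(pdist(pts)), ["g1"] * n + ["g2"] * n


class TestPermanova:
    def test_separated_clouds_maximally_significant(self):
        D, groups = _two_clouds(sep=100.0)
        res = permanova(D, groups, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r2 > 0.9

    def test_single_group_rejected(self):
        D, _ = _two_clouds(sep=1.0)
        with pytest.raises(ValueError):
            permanova(D, ["g"] * 20, seed=0)

    def test_group_of_size_one_rejected(self):
        D, _ = _two_clouds(sep=1.0)
        with pytest.raises(ValueError, match="size 1"):
            permanova(D, ["a"] + ["b"] * 19, seed=0)

    def test_pseudo_f_matches_skbio(self):
        D, groups = _two_clouds(sep=2.0, seed=3)
        ours = permanova(D, groups, n_perm=49, seed=0)
        ref = skbio_permanova(
            SkbioDM(D), grouping=list(groups), permutations=49
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_null_p_roughly_uniform(self):
        """Exchangeable labels: mean p over repeated null draws near 0.5."""
        rng = np.random.default_rng(10)
        ps = []
        for rep in range(200):
            pts = rng.normal(size=(20, 2))
            D = squareform(pdist(pts))
            res = permanova(D, ["a"] * 10 + ["b"] * 10, n_perm=99, seed=rep)
            ps.append(res.p_value)
        assert 0.45 <= np.mean(ps) <= 0.55

    def test_r2_and_p_bounds(self):
        D, groups = _two_clouds(sep=1.0, seed=5)
        res = permanova(D, groups, n_perm=99, seed=2)
        assert 0 <= res.r2 <= 1
        assert 1 / 100 <= res.p_value <= 1


class TestRda:
    def test_perfect_linear_constraint(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        Y = np.outer(x, rng.normal(size=5))
        res = rda(Y, x[:, None])
        assert res.r2 == pytest.approx(1.0)
        assert res.constrained == 1

    def test_orthogonal_constraint_no_fit(self):
        Y = np.zeros((8, 3))
        Y[:, 0] = np.tile([1.0, -1.0], 4)
        x = np.tile([1.0, 1.0, -1.0, -1.0], 2)  # orthogonal to the signal
        res = rda(Y, x[:, None])
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_identity_basis_reproduces_pca(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(12, 6))
        res = rda(Y, np.eye(12))
        Yc = Y - Y.mean(axis=0)
        pca_eigs = np.linalg.svd(Yc, compute_uv=False) ** 2 / (12 - 1)
        assert np.allclose(res.eigenvalues, pca_eigs[: len(res.eigenvalues)], atol=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_ezekiel_adjustment_unbiased_under_null(self):
        rng = np.random.default_rng(11)
        adjs = []
        for _ in range(200):
            Y = rng.normal(size=(36, 50))
            x = rng.normal(size=36)
            adjs.append(rda(Y, x[:, None]).adj_r2)
        assert abs(np.mean(adjs)) < 0.02

    def test_constant_constraint_rejected(self):
        Y = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(ValueError):
            rda(Y, np.ones((8, 1)))


class TestFactorFit:
    def test_factor_on_first_principal_direction(self):
        """A factor equal to PC1 scores explains exactly PC1's variance
        share."""
        rng = np.random.default_rng(6)
        base = rng.normal(size=(25, 8))
        Yc = base - base.mean(axis=0)
        U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
        x = U[:, 0] * s[0]
        ff = factor_fit(Yc, x, n_perm=49, seed=0)
        assert ff.r2 == pytest.approx(s[0] ** 2 / (s**2).sum(), abs=1e-9)

    def test_global_ratio_adjustment_arithmetic(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(20, 4))
        x = rng.normal(size=20)
        ff = factor_fit(Y, x, n_perm=9, seed=0, model_adj_ratio=2 / 3)
        assert ff.adj_r2_global_ratio == pytest.approx(ff.r2 * 2 / 3)
        ff2 = factor_fit(Y, np.full(20, 0.5667), n_perm=9, seed=0)
        assert np.isnan(ff2.r2)  # constant factor -> missing

    def test_global_ratio_matches_printed_style_value(self):
        # a marginal R^2 of 0.5667 scaled by a model ratio of 2/3
        assert 0.5667 * (2 / 3) == pytest.approx(0.3778, abs=1e-4)

    def test_null_factor_p_roughly_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for rep in range(100):
            Y = rng.normal(size=(18, 10))
            x = rng.normal(size=18)
            ps.append(factor_fit(Y, x, n_perm=99, seed=rep).p_value)
        assert 0.4 <= np.mean(ps) <= 0.6
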