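"""Beta diversity: distances, PCoA, group tests, Procrustes, RV machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova
from statsmodels.stats.multitest import multipletests

from micropair.ordination import (
    aitchison_distance,
    anosim,
    pairwise_permanova,
    pcoa,
    permanova,
    procrustes_r,
    rv_coefficient,
    rv_matrix,
    rv_matrix_pca,
)
from micropair.prep import clr_transform

from conftest import make_table


def _random_clr(rng, n=12, p=6):
    X = rng.uniform(0.1, 5, size=(n, p))
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                      columns=[f"t{j}" for j in range(p)])
    return clr_transform(df)


class TestAitchisonDistance:
    def test_identical_samples_distance_zero(self):
        clr = pd.DataFrame([[0.1, -0.1], [0.1, -0.1]], index=["a", "b"])
        d = aitchison_distance(clr)
        assert d["a", "b"] == pytest.approx(0.0)

    def test_two_part_closed_form(self):
        # compositions (1,1) and (1,e²): clr rows (0,0) and (−1,1), distance √2
        table = make_table({"A a": [1.0, 1.0], "B b": [1.0, float(np.e) ** 2]})
        d = aitchison_distance(clr_transform(table))
        assert d["s0", "s1"] == pytest.approx(np.sqrt(2.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.5, 3, size=(4, 5))
        t1 = make_table({f"T sp{j}": X[:, j].tolist() for j in range(5)})
        X2 = X.copy()
        X2[0] *= 10  # rescale one sample's counts
        t2 = make_table({f"T sp{j}": X2[:, j].tolist() for j in range(5)})
        d1 = aitchison_distance(clr_transform(t1))
        d2 = aitchison_distance(clr_transform(t2))
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-10)

    def test_nan_rejected(self):
        clr = pd.DataFrame([[0.0, np.nan], [0.1, -0.1]])
        with pytest.raises(ValueError, match="NaN"):
            aitchison_distance(clr)


class TestPcoa:
    def test_recovers_euclidean_points(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        res = pcoa(d)
        r, _ = procrustes_r(res.coordinates.to_numpy()[:, :2], pts, n_perm=0)
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_equilateral_triangle_equal_eigenvalues(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                           ids=["a", "b", "c"])
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_matches_pca_of_clr(self):
        rng = np.random.default_rng(2)
        clr = _random_clr(rng, n=15, p=8)
        res = pcoa(aitchison_distance(clr))
        # PCA of the clr matrix: SVD of the centred data
        C = clr.to_numpy() - clr.to_numpy().mean(axis=0)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        scores = U * s
        k = res.coordinates.shape[1]
        for j in range(k):
            a = res.coordinates.to_numpy()[:, j]
            b = scores[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_pairwise_distances_reproduced(self):
        rng = np.random.default_rng(3)
        clr = _random_clr(rng)
        d = aitchison_distance(clr)
        res = pcoa(d)
        d2 = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(d2 - d.data).max() < 1e-8


class TestAnosim:
    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 12
            d = DistanceMatrix(squareform(pdist(rng.normal(size=(n, 3)))),
                               ids=[str(i) for i in range(n)])
            groups = list(rng.choice(["a", "b", "c"], size=n))
            while min(groups.count(g) for g in set(groups)) < 2 or len(set(groups)) < 2:
                groups = list(rng.choice(["a", "b", "c"], size=n))
            r_mine, _ = anosim(d, groups, n_perm=9, seed=0)
            r_ref = skbio_anosim(d, np.array(groups), permutations=0)["test statistic"]
            assert r_mine == pytest.approx(r_ref, abs=1e-10)

    def test_separated_clusters_r_one(self):
        pts = np.vstack([np.random.default_rng(5).normal(0, 0.01, (6, 2)),
                         np.random.default_rng(6).normal(100, 0.01, (6, 2))])
        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        r, p = anosim(d, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_invariant_to_monotone_distance_transform(self):
        rng = np.random.default_rng(7)
        dd = squareform(pdist(rng.normal(size=(10, 3))))
        groups = ["a"] * 5 + ["b"] * 5
        r1, _ = anosim(DistanceMatrix(dd, ids=[str(i) for i in range(10)]),
                       groups, n_perm=9, seed=0)
        r2, _ = anosim(DistanceMatrix(np.sqrt(dd), ids=[str(i) for i in range(10)]),
                       groups, n_perm=9, seed=0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_singleton_group_rejected(self):
        d = DistanceMatrix(squareform(pdist(np.eye(4))),
                           ids=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="at least two samples"):
            anosim(d, ["x", "x", "x", "y"], n_perm=9)


class TestPermanova:
    def test_matches_skbio_pseudo_f(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 14
            d = DistanceMatrix(squareform(pdist(rng.normal(size=(n, 4)))),
                               ids=[str(i) for i in range(n)])
            groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 4
            f_mine, _ = permanova(d, groups, n_perm=9, seed=0)
            f_ref = skbio_permanova(d, np.array(groups), permutations=0)["test statistic"]
            assert f_mine == pytest.approx(f_ref, rel=1e-10)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 5))
        X[:15] += 5.0  # large mean shift in clr space
        d = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(30)])
        _, p = permanova(d, ["a"] * 15 + ["b"] * 15, n_perm=999, seed=0)
        assert p <= 0.001

    def test_pairwise_bh_adjustment(self):
        # BH on (0.01, 0.02, 0.04) → (0.03, 0.03, 0.04)
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])
        rng = np.random.default_rng(10)
        X = rng.normal(size=(18, 4))
        d = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(18)])
        pw = pairwise_permanova(d, ["a"] * 6 + ["b"] * 6 + ["c"] * 6,
                                n_perm=99, seed=0)
        assert set(zip(pw["group_a"], pw["group_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c")}
        manual = multipletests(pw["p"].to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(pw["p_adjusted"], manual)

    def test_few_permutations_warn(self):
        d = DistanceMatrix(squareform(pdist(np.eye(6))),
                           ids=[str(i) for i in range(6)])
        with pytest.warns(UserWarning, match="resolution"):
            permanova(d, ["a"] * 3 + ["b"] * 3, n_perm=9)


class TestProcrustes:
    def test_rotation_and_scale_give_r_one(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 3))
        theta = 0.7
        R = np.eye(3)
        R[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        Y = 3.2 * X @ R + 1.5
        r, _ = procrustes_r(X, Y, n_perm=0)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_symmetric(self):
        rng = np.random.default_rng(12)
        X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        r1, _ = procrustes_r(X, Y, n_perm=0)
        r2, _ = procrustes_r(Y, X, n_perm=0)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_independent_configurations_not_significant(self):
        rng = np.random.default_rng(13)
        X, Y = rng.normal(size=(40, 3)), rng.normal(size=(40, 3))
        r, p = procrustes_r(X, Y, n_perm=199, seed=0)
        assert r < 0.6
        assert p > 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            procrustes_r(np.zeros((2, 2)), np.zeros((2, 2)))


def rv_bruteforce(X, Y):
    """Double sum of squared cross-covariances over the RV formula."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    sxy = sum((X[:, i] @ Y[:, j]) ** 2
              for i in range(X.shape[1]) for j in range(Y.shape[1]))
    sxx = sum((X[:, i] @ X[:, j]) ** 2
              for i in range(X.shape[1]) for j in range(X.shape[1]))
    syy = sum((Y[:, i] @ Y[:, j]) ** 2
              for i in range(Y.shape[1]) for j in range(Y.shape[1]))
    return sxy / np.sqrt(sxx * syy)


class TestRvCoefficient:
    def test_self_rv_one(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(9, 4))
        rv, _ = rv_coefficient(X, X, n_perm=0)
        assert rv == pytest.approx(1.0)

    def test_zero_cross_covariance(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        Y = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        rv, _ = rv_coefficient(X, Y, n_perm=0)
        assert rv == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_double_sum(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            X = rng.normal(size=(10, 3))
            Y = rng.normal(size=(10, 3))
            rv, _ = rv_coefficient(X, Y, n_perm=0)
            assert rv == pytest.approx(rv_bruteforce(X, Y), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rv_coefficient(np.zeros((5, 2)), np.ones((5, 2)), n_perm=0)


class TestRvMatrixPca:
    def test_identity_matrix_equal_axes(self):
        K = pd.DataFrame(np.eye(6), index=list("abcdef"), columns=list("abcdef"))
        proj, lam = rv_matrix_pca(K)
        np.testing.assert_allclose(lam, np.ones(6))
        d = squareform(pdist(proj.to_numpy()))
        np.testing.assert_allclose(d[np.triu_indices(6, 1)], np.sqrt(2.0))

    def test_all_ones_rank_one(self):
        K = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        proj, lam = rv_matrix_pca(K)
        np.testing.assert_allclose(lam, [3, 0, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(proj["PC1"]), 1.0)
        assert np.ptp(proj["PC1"].to_numpy()) < 1e-12  # all three coincide on PC1

    def test_reconstruction_of_random_psd(self):
        rng = np.random.default_rng(16)
        A = rng.normal(size=(6, 6))
        K = A @ A.T
        K = K / np.abs(K).max()
        np.fill_diagonal(K, 1.0)
        K = (K + K.T) / 2
        lam0 = np.linalg.eigvalsh(K)
        if lam0.min() < 0:
            K = K - 2 * lam0.min() * np.eye(6)
            K = K / K[0, 0]
        proj, lam = rv_matrix_pca(pd.DataFrame(K))
        U = proj.to_numpy() / np.where(np.sqrt(lam) > 0, np.sqrt(lam), 1.0)
        recon = U @ np.diag(lam) @ U.T
        assert np.abs(recon - K).max() < 1e-8

    def test_indefinite_rejected(self):
        K = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="indefinite"):
            rv_matrix_pca(K)

    def test_rv_matrix_diagonal_and_bounds(self):
        rng = np.random.default_rng(17)
        configs = {f"d{i}": rng.normal(size=(8, 3)) for i in range(4)}
        K = rv_matrix(configs)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert ((K.to_numpy() >= 0) & (K.to_numpy() <= 1)).all()
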