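"""Correlation, clustering, PCA and CCA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qpcrmine.ctio import OIL_FEATURES, TraitTable
from qpcrmine.errors import AlignmentError, DesignError, SingularityError
from qpcrmine.multivar import cca, pca_correlation, pearson_matrix, ward_cluster


def ttable(arr, features=None, index=None):
    arr = np.asarray(arr, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[1])]
    frame = pd.DataFrame(arr, columns=features)
    if index is not None:
        frame.index = index
    return TraitTable(frame)


# ---------------------------------------------------------------- Pearson

class TestPearson:
    def test_fixture_thymol_citronellol(self, oils):
        cm = pearson_matrix(oils)
        assert round(float(cm.r.loc["thymol", "beta-citronellol"]), 2) == 0.82

    def test_self_correlation(self, oils):
        cm = pearson_matrix(oils)
        assert np.allclose(np.diag(cm.r.to_numpy()), 1.0)
        assert np.allclose(np.diag(cm.p.to_numpy()), 0.0)

    def test_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        cm = pearson_matrix(ttable(np.column_stack([x, -x])))
        assert cm.r.loc["f0", "f1"] == pytest.approx(-1.0)

    def test_p_from_t_transform(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        cm = pearson_matrix(ttable(X))
        from scipy import stats
        for i, j in itertools.combinations(range(3), 2):
            r = cm.r.iloc[i, j]
            t = r * np.sqrt(10 / (1 - r**2))
            assert cm.p.iloc[i, j] == pytest.approx(2 * stats.t.sf(abs(t), 10), abs=1e-12)

    def test_zero_variance_feature_nan_with_warning(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = pearson_matrix(ttable(X))
        assert np.isnan(cm.r.loc["f0", "f1"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(DesignError, match="3 complete rows"):
            pearson_matrix(ttable(np.random.default_rng(0).normal(size=(2, 2))))


# ---------------------------------------------------------------- Ward

class TestWard:
    def test_identical_profiles_merge_first_at_zero(self):
        X = np.array([[1.0, 5.0, 1.2, 9.0], [1.0, 5.0, 1.2, 9.0], [0.0, 1.0, 7.0, 3.0]]).T
        res = ward_cluster(ttable(X), axis="features", standardize_features=False)
        assert res.linkage[0, 2] == 0.0
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_line_points_k2_matches_exhaustive_ward_objective(self):
        # oracle: evaluate total within-cluster SS over all 2-partitions
        pts = np.array([0.0, 0.1, 0.2, 10.0, 10.1])
        table = ttable(pts.reshape(-1, 1), index=[f"p{i}" for i in range(5)])
        res = ward_cluster(table, axis="observations", standardize_features=False)
        cut = res.cut(2)
        best, best_ss = None, np.inf
        for mask in range(1, 2**4):
            members = [bool(mask & (1 << i)) for i in range(4)] + [False]
            g1 = pts[[i for i in range(5) if members[i]]]
            g2 = pts[[i for i in range(5) if not members[i]]]
            if len(g1) == 0 or len(g2) == 0:
                continue
            ss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
            if ss < best_ss:
                best_ss, best = ss, frozenset(i for i in range(5) if members[i])
        ours = frozenset(i for i, c in enumerate(cut) if c == cut.iloc[0])
        assert ours in (best, frozenset(range(5)) - best)
        assert ours in (frozenset({0, 1, 2}), frozenset({3, 4}))

    def test_fixture_oils_k3_memberships(self, oils):
        res = ward_cluster(oils, axis="features")
        cut = res.cut(3)
        assert cut["estragole"] == cut["alpha-pinene"]
        assert cut["thymol"] == cut["beta-citronellol"] == cut["1,8-cineole"]
        assert cut["carvone"] not in (cut["estragole"], cut["thymol"])

    def test_heights_nondecreasing_and_leaf_order_valid(self, oils):
        res = ward_cluster(oils, axis="features")
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert sorted(res.leaf_order) == list(range(len(oils.features)))

    def test_feature_order_invariance_when_standardized(self, oils):
        res1 = ward_cluster(oils, axis="observations")
        shuffled = oils.subset(list(reversed(oils.features)))
        res2 = ward_cluster(shuffled, axis="observations")
        assert np.allclose(np.sort(res1.linkage[:, 2]), np.sort(res2.linkage[:, 2]))
        assert (res1.cut(3).to_numpy() == res2.cut(3).to_numpy()).all()

    def test_constant_feature_rejected_under_standardization(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DesignError, match="f0"):
            ward_cluster(ttable(X), axis="features")

    def test_newick_string_shape(self, oils):
        tree = ward_cluster(oils, axis="features").newick()
        assert tree.endswith(";") and tree.count("(") == len(oils.features) - 1


# ---------------------------------------------------------------- PCA

class TestPca:
    def test_perfectly_correlated_pair_pc1_explains_all(self):
        x = np.arange(6.0)
        res = pca_correlation(ttable(np.column_stack([x, 2 * x + 1])))
        assert res.explained.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_equal_variance_isotropic(self):
        # orthogonal design: two exactly uncorrelated features
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        res = pca_correlation(ttable(np.column_stack([x, y])))
        assert np.allclose(res.explained.to_numpy(), 0.5)

    def test_small_matrix_matches_direct_eigendecomposition(self):
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 1.5], [3.0, 5.0, 0.0], [4.0, 3.0, 2.0]])
        res = pca_correlation(ttable(X))
        corr = np.corrcoef((X - X.mean(0)) / X.std(0, ddof=1), rowvar=False)
        eigval = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(res.explained.to_numpy() * eigval.sum(), eigval, atol=1e-10)
        # loadings are eigenvectors: corr @ v = lambda v
        for k in range(3):
            v = res.loadings.iloc[:, k].to_numpy()
            lam = eigval[k]
            assert np.allclose(corr @ v, lam * v, atol=1e-8)

    def test_explained_sums_to_one_and_reconstruction(self, oils):
        res = pca_correlation(oils)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-10)
        Z = (oils.values - oils.values.mean()) / oils.values.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Z.to_numpy(), atol=1e-8)
        # loadings orthonormal
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_insufficient_observations(self):
        with pytest.raises(DesignError):
            pca_correlation(ttable(np.random.default_rng(0).normal(size=(2, 3))))


# ---------------------------------------------------------------- CCA

def grid_search_cca_2x2(X, Y, coarse=720):
    """Dense direction-grid oracle for canonical correlations of 2+2 sets."""
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)

    def corr_grid(angles_a, angles_b):
        A = np.stack([np.cos(angles_a), np.sin(angles_a)])
        B = np.stack([np.cos(angles_b), np.sin(angles_b)])
        U, V = X @ A, Y @ B
        U = U - U.mean(0)
        V = V - V.mean(0)
        num = U.T @ V
        den = np.sqrt((U**2).sum(0))[:, None] * np.sqrt((V**2).sum(0))[None, :]
        return np.abs(num / den)

    ta = np.linspace(0, np.pi, coarse, endpoint=False)
    grid = corr_grid(ta, ta)
    i, j = np.unravel_index(np.argmax(grid), grid.shape)
    # local refinement around the coarse optimum
    fa = np.linspace(ta[i] - np.pi / coarse, ta[i] + np.pi / coarse, 400)
    fb = np.linspace(ta[j] - np.pi / coarse, ta[j] + np.pi / coarse, 400)
    fine = corr_grid(fa, fb)
    k, l = np.unravel_index(np.argmax(fine), fine.shape)
    cc1 = fine[k, l]
    a1 = np.array([np.cos(fa[k]), np.sin(fa[k])])
    b1 = np.array([np.cos(fb[l]), np.sin(fb[l])])
    # second pair: unique directions S-orthogonal to the first, in 2D
    Sxx = np.cov(X, rowvar=False)
    Syy = np.cov(Y, rowvar=False)
    a2 = np.array([-(Sxx @ a1)[1], (Sxx @ a1)[0]])
    b2 = np.array([-(Syy @ b1)[1], (Syy @ b1)[0]])
    u, v = X @ a2, Y @ b2
    cc2 = abs(np.corrcoef(u, v)[0, 1])
    return cc1, cc2


class TestCca:
    def test_identical_sets_all_correlations_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        res = cca(ttable(X), ttable(X.copy()))
        assert np.allclose(res.correlations, 1.0, atol=1e-8)

    def test_single_pair_reduces_to_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(size=12)
        res = cca(ttable(x.reshape(-1, 1)), ttable(y.reshape(-1, 1)))
        assert res.correlations[0] == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_fixed_2plus2_instance_matches_grid_search(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 2))
        Y = np.column_stack([X[:, 0] * 0.8 + rng.normal(size=8) * 0.4,
                             rng.normal(size=8)])
        res = cca(ttable(X), ttable(Y))
        cc1, cc2 = grid_search_cca_2x2(X, Y)
        assert res.correlations[0] == pytest.approx(cc1, abs=1e-3)
        assert res.correlations[1] == pytest.approx(cc2, abs=1e-3)

    def test_first_correlation_bounds_all_cross_pairs(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        Y = rng.normal(size=(12, 2))
        res = cca(ttable(X), ttable(Y))
        cross = np.abs(np.corrcoef(np.hstack([X, Y]), rowvar=False)[:3, 3:])
        assert res.correlations[0] >= cross.max() - 1e-10
        assert (np.diff(res.correlations) <= 1e-10).all()

    def test_diagonal_scaling_invariance_unregularized(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 3))
        Y = rng.normal(size=(15, 2))
        base = cca(ttable(X), ttable(Y))
        scaled = cca(ttable(X * np.array([3.0, 0.2, 11.0])), ttable(Y * np.array([0.5, 9.0])))
        assert np.allclose(base.correlations, scaled.correlations, atol=1e-10)

    def test_row_mismatch_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        a = ttable(X, index=list("abcdef"))
        b = ttable(X, index=list("abcdeg"))
        with pytest.raises(AlignmentError):
            cca(a, b)

    def test_singular_requires_ridge(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 6))  # p > n: within-set correlation is singular
        Y = rng.normal(size=(5, 2))
        with pytest.raises(SingularityError, match="ridge"):
            cca(ttable(X), ttable(Y))
        res = cca(ttable(X), ttable(Y), ridge=1e-3)
        assert len(res.correlations) == 2
        assert res.wilks["p"].isna().all()  # significance suppressed under ridge

    def test_fixture_sets_need_regularization_to_avoid_overfit(self, table1, table2):
        # 11 + 6 variables on 15 rows: unregularized canonical correlations
        # saturate near 1; the default ridge keeps them interpretable
        res = cca(table1, table2, ridge=1e-3)
        assert len(res.correlations) == 6
        assert (res.correlations <= 1.0).all() and (np.diff(res.correlations) <= 1e-10).all()
        assert res.wilks["p"].isna().all()

    def test_bartlett_significance_unregularized(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        Y = np.column_stack([X[:, 0] + rng.normal(size=40) * 0.3, rng.normal(size=40)])
        res = cca(ttable(X), ttable(Y))
        assert res.wilks.loc["CC1", "p"] < 0.01
        assert 0 <= res.wilks.loc["CC2", "p"] <= 1


# ---------------------------------------------------------------- cross-set

def test_fixture_cross_set_expression_vs_content(table1, table2):
    """TPS27 expression tracks 1,8-cineole content across the 15 treatments."""
    joined = TraitTable(
        pd.concat([table2.values[["TPS27"]], table1.values[["1,8-cineole"]]], axis=1)
    )
    cm = pearson_matrix(joined)
    assert round(float(cm.r.loc["TPS27", "1,8-cineole"]), 2) == 0.84
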