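"""PCA, Procrustes disparity, genericity and the Monte-Carlo random baseline."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes as scipy_procrustes

import matsig as ms
from matsig.structure import _standardize


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _grid_search_disparity(X, Y, step=1e-4):
    """Independent oracle: standardized disparity by brute-force search over
    a rotation-angle grid and both reflections (2-D only).  For each candidate
    rotation the optimal scale is b = <X R, Y> (X has unit norm), and the
    residual ||b X R - Y||^2 is evaluated directly."""
    Xs, _, _ = _standardize(X)
    Ys, _, _ = _standardize(Y)
    thetas = np.arange(0.0, 2 * np.pi, step)
    R = np.empty((len(thetas), 2, 2))
    R[:, 0, 0] = R[:, 1, 1] = np.cos(thetas)
    R[:, 1, 0] = np.sin(thetas)
    R[:, 0, 1] = -R[:, 1, 0]
    best = np.inf
    for mirrored in (False, True):
        Xm = Xs @ np.diag([1.0, -1.0]) if mirrored else Xs
        XR = np.einsum("nj,tjk->tnk", Xm, R)
        b = np.einsum("tnk,nk->t", XR, Ys)
        d = ((b[:, None, None] * XR - Ys) ** 2).sum(axis=(1, 2))
        best = min(best, d.min())
    return float(best)


class TestFitPCA:
    def test_collinear_columns_rank_one(self):
        x = np.linspace(0, 1, 20)
        model = ms.fit_pca(np.column_stack([x, 2 * x + 1]), k=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one(self, default_run):
        model = ms.fit_pca(default_run["means"])
        evr = model.explained_variance_ratio
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(evr) <= 1e-12).all()

    def test_matches_eigendecomposition_oracle(self):
        """6 x 4 toy matrix vs explicit covariance eigendecomposition."""
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (6, 4)) * [1, 3, 0.5, 2] + [10, -5, 0, 2]
        model = ms.fit_pca(X, center=True, scale=True)
        Z = (X - X.mean(0)) / X.std(0)
        w, V = np.linalg.eigh(Z.T @ Z / len(Z))
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        np.testing.assert_allclose(model.explained_variance_ratio, w / w.sum(), atol=1e-8)
        for j in range(4):
            got = model.loadings.to_numpy()[:, j]
            ref = V[:, j]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8

    def test_scores_reconstruct_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 2, (30, 5))
        model = ms.fit_pca(X, center=True, scale=True)
        Z = (X - model.center) / model.scale
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.abs(recon - Z).max() < 1e-8

    def test_scores_uncorrelated(self, default_run):
        model = ms.fit_pca(default_run["means"])
        S = model.scores.to_numpy()
        cov = np.cov(S.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention(self, default_run):
        model = ms.fit_pca(default_run["means"])
        L = model.loadings.to_numpy()
        assert (L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])] > 0).all()

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            ms.fit_pca(X, scale=True)


class TestMaterialPCA:
    def test_default_material_has_30_rows(self, default_run):
        model = ms.material_pca(default_run["means"], "wood", k=2)
        assert model.scores.shape == (30, 2)

    def test_single_material_equals_global(self, default_run):
        means = default_run["means"]
        sub = means[means["material"] == "wood"]
        a = ms.material_pca(sub, "wood")
        b = ms.fit_pca(sub)
        np.testing.assert_allclose(a.loadings.to_numpy(), b.loadings.to_numpy(), atol=1e-10)

    def test_constructed_axis_recovered(self):
        """Anisotropic within-material variance: first loading direction
        recovers the constructed axis within 10 degrees."""
        rng = np.random.default_rng(2)
        axis = np.array([3.0, 1.0, -2.0, 0.5])
        axis /= np.linalg.norm(axis)
        pts = 50 + np.outer(rng.normal(0, 12, 40), axis) + rng.normal(0, 1.0, (40, 4))
        means = pd.DataFrame(pts, columns=list("abcd"))
        means.insert(0, "material", "wood")
        model = ms.material_pca(means, "wood", k=1, scale=False)
        v = model.loadings.to_numpy()[:, 0]
        angle = np.degrees(np.arccos(min(1.0, abs(v @ axis))))
        assert angle < 10

    def test_too_few_rows_rejected(self):
        means = pd.DataFrame({"material": ["wood"] * 2, "a": [1.0, 2], "b": [3.0, 4]})
        with pytest.raises(ValueError, match="need >= 3"):
            ms.material_pca(means, "wood")


class TestProcrustesDisparity:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (10, 2))
        d, _ = ms.procrustes_disparity(X, X)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_similarity_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (12, 2))
        Y = 2.3 * X @ _rot(np.radians(37)).T + np.array([5.0, -7.0])
        d, _ = ms.procrustes_disparity(X, Y)
        assert d == pytest.approx(0.0, abs=1e-10)

    def test_reflection_allowed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (8, 2))
        d, _ = ms.procrustes_disparity(X, X @ np.diag([1.0, -1.0]))
        assert d == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (10, 2)])
    def test_matches_grid_search_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, 2))
        Y = rng.normal(0, 1, (n, 2))
        d, _ = ms.procrustes_disparity(X, Y)
        oracle = _grid_search_disparity(X, Y, step=1e-4)
        assert d == pytest.approx(oracle, abs=1e-6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        X, Y = rng.normal(0, 1, (9, 2)), rng.normal(0, 1, (9, 2))
        d, _ = ms.procrustes_disparity(X, Y)
        _, _, ref = scipy_procrustes(Y, X)   # scipy maps 2nd arg onto 1st
        assert d == pytest.approx(ref, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        X, Y = rng.normal(0, 1, (15, 2)), rng.normal(0, 1, (15, 2))
        assert ms.procrustes_disparity(X, Y)[0] == pytest.approx(
            ms.procrustes_disparity(Y, X)[0], abs=1e-10)

    def test_degenerate_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="degenerate|coincident"):
            ms.procrustes_disparity(X, np.random.default_rng(8).normal(0, 1, (5, 2)))


class TestGenericity:
    def test_full_dimensional_residual_is_zero(self, default_run):
        """With every component retained, the material-specific PCA is a rigid
        rotation of the same points: residual exactly 0 for all materials."""
        means = default_run["means"]
        full = ms.fit_pca(means, k=10)
        for g in ms.genericity(full, means, k=10):
            assert g.residual == pytest.approx(0.0, abs=1e-8)

    def test_rank2_single_material_residual_zero(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, (30, 2))
        basis = np.linalg.qr(rng.normal(0, 1, (4, 2)))[0]
        pts = 50 + scores @ basis.T * 10
        means = pd.DataFrame(pts, columns=list("abcd"),
                             index=[f"wood_{i}" for i in range(30)])
        means.insert(0, "material", "wood")
        model = ms.fit_pca(means, k=2)
        g = ms.genericity(model, means, k=2)
        assert g[0].residual == pytest.approx(0.0, abs=1e-8)

    @staticmethod
    def _outlier_means(seed):
        """8 materials varying in the global (a, b) plane plus one 'odd'
        material varying only in the orthogonal (e, f) plane."""
        rng = np.random.default_rng(seed)
        n_attr, per_mat = 6, 30
        frames = []
        for i in range(8):
            base = np.zeros(n_attr)
            base[:2] = rng.normal(0, 20, 2)
            dev = np.zeros((per_mat, n_attr))
            dev[:, :2] = rng.normal(0, 6, (per_mat, 2))     # in-plane variation
            dev += rng.normal(0, 0.5, dev.shape)
            m = f"mat{i}"
            frames.append(pd.DataFrame(50 + base + dev, columns=list("abcdef"),
                                       index=[f"{m}_{j}" for j in range(per_mat)]
                                       ).assign(material=m))
        out = np.zeros((per_mat, n_attr))
        out[:, 4:] = rng.normal(0, 6, (per_mat, 2))          # orthogonal plane
        out += rng.normal(0, 0.5, out.shape)
        frames.append(pd.DataFrame(50 + out, columns=list("abcdef"),
                                   index=[f"odd_{j}" for j in range(per_mat)]
                                   ).assign(material="odd"))
        return pd.concat(frames)[["material"] + list("abcdef")]

    def test_constructed_outlier_material(self):
        """A material varying in a subspace orthogonal to the global structure
        gets a larger residual than the median material, in every replicate."""
        for seed in range(10):
            means = self._outlier_means(seed)
            model = ms.fit_pca(means, k=2, scale=False)
            res = {g.material: g.residual for g in ms.genericity(model, means, k=2)}
            med = np.median([v for k, v in res.items() if k != "odd"])
            assert res["odd"] > med

    def test_residuals_below_random_baseline(self, design, default_run):
        """Real (simulated) materials are all more generic than uniform noise."""
        means = default_run["means"]
        model = ms.fit_pca(means, k=2)
        table = ms.genericity_with_baseline(model, means, n_reps=300, seed=1)
        assert (table["residual"] < table["baseline_mean"]).all()


class TestRandomBaseline:
    def test_grand_mean_near_printed_value(self, default_run):
        """30-point uniform configurations onto each material subset average
        ~0.95 standardized disparity."""
        means = default_run["means"]
        model = ms.fit_pca(means, k=2)
        _, grand = ms.random_baseline(model, means, n_reps=2000, seed=2)
        assert grand == pytest.approx(0.9508, abs=0.02)

    def test_vectorized_path_matches_procrustes_disparity(self, default_run):
        """Internal closed-form 2x2 disparity equals the SVD implementation."""
        means = default_run["means"]
        model = ms.fit_pca(means, k=2)
        sub = means[means["material"] == "wood"]
        tgt = model.scores.loc[sub.index].to_numpy()
        rng = np.random.default_rng(3)
        for _ in range(50):
            X = rng.uniform(0, 1, (30, 2))
            d, _ = ms.procrustes_disparity(X, tgt)
            Xs, _, _ = _standardize(X)
            Ys, _, _ = _standardize(tgt)
            M = Xs.T @ Ys
            closed = 1 - ((M**2).sum() + 2 * abs(np.linalg.det(M)))
            assert d == pytest.approx(closed, abs=1e-10)

    def test_copy_of_target_gives_zero(self, default_run):
        means = default_run["means"]
        model = ms.fit_pca(means, k=2)
        sub = means.index[means["material"] == "wood"]
        tgt = model.scores.loc[sub].to_numpy()
        assert ms.procrustes_disparity(tgt.copy(), tgt)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_monte_carlo_oracle(self):
        """Mean disparity of random-onto-random at n=30 via a separate RNG and
        a direct scipy-procrustes loop, within 3 SE."""
        rng_a = np.random.default_rng(12345)
        tgt = rng_a.uniform(0, 1, (30, 2))
        means = pd.DataFrame(np.c_[tgt, tgt], columns=list("wxyz"),
                             index=[f"wood_{i}" for i in range(30)])
        means.insert(0, "material", "wood")
        model = ms.fit_pca(means, k=2, scale=True)
        table, grand = ms.random_baseline(model, means, n_reps=4000, seed=99)
        rng_b = np.random.RandomState(777)     # independent legacy RNG
        ref_target = model.scores.to_numpy()
        ds = []
        for _ in range(4000):
            X = rng_b.uniform(0, 1, (30, 2))
            _, _, d = scipy_procrustes(ref_target, X)
            ds.append(d)
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        pooled_se = se * np.sqrt(2)
        assert grand == pytest.approx(np.mean(ds), abs=3 * pooled_se)
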