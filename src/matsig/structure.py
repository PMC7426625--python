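"""Attribute-space structure: PCA and the Procrustes "genericity" analysis.

The stimulus-means matrix (stimuli x attributes) is decomposed by PCA, both
globally (all stimuli) and per material (that material's stimuli only).  For
each material, its material-specific two-component scores are mapped onto the
corresponding rows of the global two-component score space by a full
Procrustes superimposition (translation, scaling, rotation and reflection);
the standardized residual disparity measures how much that material's
internal perceptual structure deviates from the global between-material
structure.  Low residual = "generic" material.

The residual is compared to a Monte-Carlo baseline: configurations of the
same size drawn i.i.d. from a uniform 2-D distribution, mapped onto the same
targets.  For 30-point configurations the baseline averages ~0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .design import StudyDesign
from .signatures import attribute_matrix


@dataclass
class PCAModel:
    """Fitted principal-component model of an attribute space.

    ``loadings`` (attributes x components) and ``scores`` (stimuli x
    components) cover the ``k`` retained components;
    ``explained_variance_ratio`` covers *all* components and sums to 1.
    Component signs follow the convention that the largest-magnitude loading
    of each component is positive.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    centered: bool = True
    scaled: bool = True

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class ProcrustesTransform:
    rotation: np.ndarray     # orthogonal (may include reflection)
    scale: float
    translation: np.ndarray  # applied after rotation/scaling, in target units


@dataclass(frozen=True)
class GenericityResult:
    material: str
    residual: float
    baseline_mean: float | None = None
    baseline_sd: float | None = None
    n_baseline_reps: int | None = None


def fit_pca(matrix: pd.DataFrame | np.ndarray, k: int | None = None,
            center: bool = True, scale: bool = True) -> PCAModel:
    """PCA of a stimuli x attributes matrix.

    Columns are centred and (by default) scaled to unit variance before the
    decomposition, so attributes with different spreads on the shared 0-100
    slider contribute equally.  The first ``k`` components are retained
    (all, when ``k`` is None).
    """
    if isinstance(matrix, pd.DataFrame):
        X = attribute_matrix(matrix)
        cols, idx = list(X.columns), X.index
        X = X.to_numpy(float)
    else:
        X = np.asarray(matrix, float)
        cols = [f"x{j+1}" for j in range(X.shape[1])]
        idx = pd.RangeIndex(X.shape[0])
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite entries")

    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    sd = X.std(axis=0, ddof=0) if scale else np.ones(X.shape[1])
    if scale and np.any(sd == 0):
        bad = [cols[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance columns under standardization: {bad}")
    Z = (X - mean) / sd

    n_comp = min(Z.shape)
    pca = _SkPCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T          # attributes x components

    # sign convention: largest-|loading| entry positive per component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    k = n_comp if k is None else min(k, n_comp)
    comp_names = [f"PC{j+1}" for j in range(k)]
    return PCAModel(
        loadings=pd.DataFrame(loadings[:, :k], index=cols, columns=comp_names),
        scores=pd.DataFrame(scores[:, :k], index=idx, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        center=mean, scale=sd, centered=center, scaled=scale,
    )


def material_pca(means: pd.DataFrame, material: str, k: int | None = None,
                 center: bool = True, scale: bool = True) -> PCAModel:
    """PCA restricted to one material's stimuli (same preprocessing as global)."""
    if "material" not in means.columns:
        raise ValueError("means table lacks a 'material' column")
    sub = means[means["material"] == material]
    if len(sub) < 3:
        raise ValueError(f"material {material!r} has {len(sub)} stimuli; need >= 3")
    return fit_pca(sub, k=k, center=center, scale=scale)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre a configuration and scale to unit Frobenius norm."""
    X = np.asarray(X, float)
    c = X.mean(axis=0)
    Xc = X - c
    nrm = np.linalg.norm(Xc)
    if nrm == 0:
        raise ValueError("degenerate configuration: all points coincident")
    return Xc / nrm, c, nrm


def procrustes_disparity(source: np.ndarray, target: np.ndarray
                         ) -> tuple[float, ProcrustesTransform]:
    """Standardized full-Procrustes disparity between two point configurations.

    Both configurations are centred and scaled to unit total variation; the
    source is then optimally rotated/reflected and scaled onto the target.
    The residual is the remaining sum of squared point-wise differences,
    ``1 - (sum of singular values of X'Y)^2``, in [0, 1].  Symmetric in its
    arguments under this convention.
    """
    X = np.asarray(source, float)
    Y = np.asarray(target, float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    Xs, _, xnrm = _standardize(X)
    Ys, yc, ynrm = _standardize(Y)
    U, s, Vt = np.linalg.svd(Xs.T @ Ys)
    R = U @ Vt
    b = s.sum()
    disparity = float(max(1.0 - b * b, 0.0))
    transform = ProcrustesTransform(rotation=R, scale=b * ynrm / xnrm, translation=yc)
    return disparity, transform


def genericity(global_model: PCAModel, means: pd.DataFrame, k: int = 2
               ) -> list[GenericityResult]:
    """Per-material Procrustes residual of the material PCA onto the global PCA.

    For each material, a material-specific PCA is fitted to that material's
    rows of the *globally preprocessed* data (re-centred within the material
    but not re-scaled, so global and local score spaces are orthogonal views
    of the same points), and its ``k``-component scores are mapped onto the
    same stimuli's rows of the global ``k``-component score space.  A ``k``
    equal to the full attribute dimensionality therefore gives residual
    exactly 0 for every material.
    """
    if global_model.k < k:
        raise ValueError(f"global model retains {global_model.k} < {k} components")
    X = attribute_matrix(means).to_numpy(float)
    Z = (X - global_model.center) / global_model.scale
    results = []
    for m in means["material"].unique():
        rows = np.flatnonzero((means["material"] == m).to_numpy())
        if len(rows) < 3:
            raise ValueError(f"material {m!r} has {len(rows)} stimuli; need >= 3")
        local = fit_pca(Z[rows], k=k, center=True, scale=False)
        src = local.scores.to_numpy()[:, :k]
        tgt = global_model.scores.iloc[rows].to_numpy()[:, :k]
        d, _ = procrustes_disparity(src, tgt)
        results.append(GenericityResult(material=m, residual=d))
    return results


def random_baseline(global_model: PCAModel, means: pd.DataFrame,
                    n_reps: int = 10_000, seed: int = 0, k: int = 2
                    ) -> tuple[pd.DataFrame, float]:
    """Monte-Carlo uniform-random Procrustes baseline.

    For each material, ``n_reps`` configurations of the material's size are
    drawn i.i.d. uniform on the 2-D unit square and mapped onto that
    material's rows of the global score space; disparities are averaged
    within material and then across materials.  (The square's location and
    scale are irrelevant under the standardized disparity.)

    Returns (per-material frame with ``material, baseline_mean, baseline_sd``,
    grand mean across materials).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for m in means["material"].unique():
        sub_idx = means.index[means["material"] == m]
        tgt = global_model.scores.loc[sub_idx].to_numpy()[:, :k]
        n = tgt.shape[0]
        Ys, _, _ = _standardize(tgt)
        # vectorized standardized disparity against a fixed unit-norm target:
        # 1 - (sum of singular values of X'Y)^2, with the 2x2 closed form
        # (s1+s2)^2 = ||M||_F^2 + 2|det M|
        draws = rng.uniform(0.0, 1.0, size=(n_reps, n, k))
        draws -= draws.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(draws, axis=(1, 2), keepdims=True)
        draws /= nrm
        M = np.einsum("rij,ik->rjk", draws, Ys)
        if k == 2:
            ssum_sq = (M**2).sum(axis=(1, 2)) + 2.0 * np.abs(
                M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0])
        else:
            ssum_sq = np.array([np.linalg.svd(Mi, compute_uv=False).sum()**2 for Mi in M])
        disp = np.clip(1.0 - ssum_sq, 0.0, None)
        rows.append({"material": m, "baseline_mean": float(disp.mean()),
                     "baseline_sd": float(disp.std(ddof=1)) if n_reps > 1 else 0.0,
                     "n_reps": n_reps})
    table = pd.DataFrame(rows)
    return table, float(table["baseline_mean"].mean())


def genericity_with_baseline(global_model: PCAModel, means: pd.DataFrame,
                             n_reps: int = 10_000, seed: int = 0, k: int = 2
                             ) -> pd.DataFrame:
    """Genericity residuals joined with their Monte-Carlo random baseline."""
    res = pd.DataFrame([{"material": g.material, "residual": g.residual}
                        for g in genericity(global_model, means, k=k)])
    base, _ = random_baseline(global_model, means, n_reps=n_reps, seed=seed, k=k)
    return res.merge(base, on="material")
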