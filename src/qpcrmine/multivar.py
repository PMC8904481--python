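"""Multivariate mining of treatment-mean profiles.

Four views of a treatment × feature matrix (typically the 15 PEG × proline
treatment means):

* Pearson correlation matrix with per-pair two-sided p-values;
* Ward/Euclidean agglomerative clustering of features or observations
  (the ordering behind clustered heatmaps);
* PCA of the feature correlation matrix with biplot coordinates;
* canonical correlation analysis (CCA) between two feature sets sharing
  the same observations, ridge-regularized because treatment-mean designs
  often have fewer rows than combined variables.

All routines run on treatment means by default (clustering 15 rows, not
replicate-level data); pass a replicate-level TraitTable to override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .ctio import TraitTable
from .errors import AlignmentError, DesignError, SingularityError


@dataclass(frozen=True)
class CorrMatrix:
    """Pearson r over feature pairs with two-sided p-values and n per pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        """Boolean mask: p < alpha (diagonal True by convention, r = 1)."""
        return self.p < self.alpha


@dataclass(frozen=True)
class ClusterResult:
    """Ward merge sequence over one axis of a trait table.

    ``linkage`` is a scipy linkage matrix (n−1 merges, non-decreasing
    heights); ``labels`` names the clustered items in input order;
    ``leaf_order`` is the dendrogram's left-to-right permutation.
    """

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[int]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster ids (1..k) per item, from cutting the dendrogram."""
        ids = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(ids, index=self.labels, name="cluster")

    def newick(self) -> str:
        """The merge tree as a Newick string (heights as branch lengths)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return str(self.labels[node.id]).replace(",", "_").replace(" ", "_")
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


@dataclass(frozen=True)
class PcaResult:
    """PCA of the feature correlation matrix.

    ``loadings`` columns are unit eigenvectors (PC1, PC2, ...);
    ``scores`` are the z-scored observations projected on them;
    ``explained`` are eigenvalue fractions (non-increasing, summing to 1).
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained: pd.Series

    def biplot_coords(self, scale: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(observation points, feature arrows) on the first two components."""
        pts = self.scores.iloc[:, :2]
        ev = self.explained * self.loadings.shape[0]
        arrows = self.loadings.iloc[:, :2] * np.sqrt(ev.iloc[:2].to_numpy()) * scale
        return pts, arrows


@dataclass(frozen=True)
class CcaResult:
    """Canonical correlations and coefficient vectors for two feature sets.

    ``correlations`` are descending in [0, 1]; ``x_coef``/``y_coef``
    columns give the canonical directions per dimension; ``x_scores`` /
    ``y_scores`` are the canonical variates of the observations.
    ``wilks`` holds Bartlett's chi-square test per dimension (NaN when
    ridge-regularized, where the null distribution no longer applies).
    """

    correlations: np.ndarray
    x_coef: pd.DataFrame
    y_coef: pd.DataFrame
    x_scores: pd.DataFrame
    y_scores: pd.DataFrame
    wilks: pd.DataFrame
    ridge: float


def pearson_matrix(table: TraitTable, alpha: float = 0.05) -> CorrMatrix:
    """Pairwise Pearson correlations with t-transform p-values.

    Each pair uses its complete observation rows (pairwise deletion);
    p = 2·P(T_{n−2} > |t|) with t = r·√((n−2)/(1−r²)).  Zero-variance
    features yield NaN r with a warning rather than an error.
    """
    X = table.values
    feats = list(X.columns)
    k = len(feats)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    const = [f for f in feats if X[f].dropna().nunique() <= 1]
    if const:
        warnings.warn(f"zero-variance feature(s), correlations undefined: {const}", stacklevel=2)
    for i in range(k):
        for j in range(i, k):
            pair = X.iloc[:, [i, j]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if i == j:
                r[i, i] = 1.0
                p[i, i] = 0.0
                continue
            if len(pair) < 3:
                raise DesignError(
                    f"need >= 3 complete rows for ({feats[i]!r}, {feats[j]!r}), got {len(pair)}"
                )
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rij, pij = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = pd.Index(feats)
    return CorrMatrix(
        pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx), pd.DataFrame(n, idx, idx), alpha
    )


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, sd 1, ddof=1); constant columns rejected."""
    sd = values.std(ddof=1)
    const = sd.index[(sd == 0) | sd.isna()].tolist()
    if const:
        raise DesignError(f"constant feature(s) cannot be standardized: {const}")
    return (values - values.mean()) / sd


def ward_cluster(
    table: TraitTable, axis: str = "features", standardize_features: bool = True
) -> ClusterResult:
    """Ward's minimum-variance clustering on Euclidean distances.

    ``axis="features"`` clusters the feature profiles (each feature is a
    point in treatment space, the heatmap's column tree);
    ``axis="observations"`` clusters treatments.  Features are z-scored
    first by default since trait tables mix units.  Uses the ward.D2-style
    criterion on Euclidean input distances; ties resolved by scipy's
    deterministic lowest-index rule.
    """
    if axis not in ("features", "observations"):
        raise DesignError(f"axis must be 'features' or 'observations', got {axis!r}")
    values = table.values
    if standardize_features:
        values = standardize(values)
    if values.isna().any().any():
        raise DesignError("missing values present after standardization")
    if axis == "features":
        points = values.T
        labels = [str(c) for c in values.columns]
    else:
        points = values
        labels = ["_".join(map(str, t)) if isinstance(t, tuple) else str(t) for t in values.index]
    if len(points) < 2:
        raise DesignError("need at least 2 items to cluster")
    linkage = hierarchy.linkage(pdist(points.to_numpy(float)), method="ward")
    leaf_order = hierarchy.leaves_list(linkage).tolist()
    return ClusterResult(linkage=linkage, labels=labels, leaf_order=leaf_order)


def pca_correlation(table: TraitTable) -> PcaResult:
    """PCA via eigendecomposition of the feature correlation matrix.

    Equivalent to PCA of z-scored data; appropriate when features carry
    different units.  Scores are the standardized observations projected
    on the unit eigenvectors; explained fractions are eigenvalues over
    their sum.
    """
    values = table.values
    if values.shape[1] < 2:
        raise DesignError("PCA needs at least 2 features")
    if values.shape[0] < 3:
        raise DesignError("PCA needs at least 3 observations")
    if values.isna().any().any():
        raise DesignError("missing values are not supported")
    Z = standardize(values)
    corr = np.corrcoef(Z.to_numpy(float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading positive, for determinism
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    pcs = [f"PC{i+1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=values.columns, columns=pcs)
    scores = pd.DataFrame(Z.to_numpy(float) @ eigvec, index=values.index, columns=pcs)
    explained = pd.Series(eigval / eigval.sum(), index=pcs, name="explained")
    return PcaResult(loadings=loadings, scores=scores, explained=explained)


def cca(set_x: TraitTable, set_y: TraitTable, ridge: float = 0.0) -> CcaResult:
    """Canonical correlation analysis between two aligned feature sets.

    Variables are standardized, then the canonical correlations are the
    singular values of the whitened cross-correlation
    R_xx^{−1/2} R_xy R_yy^{−1/2}; ``ridge`` adds λI to both within-set
    correlation matrices before whitening, required whenever n ≤ p or
    n ≤ q makes them singular.  Per-dimension significance (Bartlett's
    chi-square approximation of Wilks' Λ) is reported only for the
    unregularized case with positive degrees of freedom.
    """
    if not set_x.values.index.equals(set_y.values.index):
        raise AlignmentError("the two sets must share identical observation rows")
    if ridge < 0:
        raise DesignError(f"ridge must be >= 0, got {ridge}")
    X = standardize(set_x.values).to_numpy(float)
    Y = standardize(set_y.values).to_numpy(float)
    n_obs, p = X.shape
    q = Y.shape[1]
    Rxx = np.corrcoef(X, rowvar=False).reshape(p, p)
    Ryy = np.corrcoef(Y, rowvar=False).reshape(q, q)
    Rxy = (X.T @ Y) / (n_obs - 1)
    if ridge == 0.0:
        for name, mat in (("x", Rxx), ("y", Ryy)):
            if np.linalg.matrix_rank(mat, tol=1e-10) < mat.shape[0]:
                raise SingularityError(
                    f"within-set covariance of set_{name} is singular "
                    "(n <= number of variables?); pass ridge > 0 to regularize"
                )
    Rxx_r = Rxx + ridge * np.eye(p)
    Ryy_r = Ryy + ridge * np.eye(q)

    def inv_sqrt(mat: np.ndarray) -> np.ndarray:
        val, vec = np.linalg.eigh(mat)
        if (val <= 1e-12).any():
            raise SingularityError("within-set covariance not positive definite; increase ridge")
        return vec @ np.diag(1.0 / np.sqrt(val)) @ vec.T

    Wx, Wy = inv_sqrt(Rxx_r), inv_sqrt(Ryy_r)
    U, s, Vt = np.linalg.svd(Wx @ Rxy @ Wy)
    d = min(p, q)
    corrs = np.clip(s[:d], 0.0, 1.0)
    a = Wx @ U[:, :d]   # canonical coefficients, standardized-variable scale
    b = Wy @ Vt.T[:, :d]
    for j in range(d):  # deterministic sign: largest x-coefficient positive
        pivot = np.argmax(np.abs(a[:, j]))
        if a[pivot, j] < 0:
            a[:, j] = -a[:, j]
            b[:, j] = -b[:, j]
    dims = [f"CC{i+1}" for i in range(d)]
    x_coef = pd.DataFrame(a, index=set_x.values.columns, columns=dims)
    y_coef = pd.DataFrame(b, index=set_y.values.columns, columns=dims)
    x_scores = pd.DataFrame(X @ a, index=set_x.values.index, columns=dims)
    y_scores = pd.DataFrame(Y @ b, index=set_y.values.index, columns=dims)
    wilks = _bartlett_wilks(corrs, n_obs, p, q) if ridge == 0.0 else pd.DataFrame(
        {"wilks_lambda": np.nan, "chi2": np.nan, "df": np.nan, "p": np.nan}, index=dims
    )
    return CcaResult(
        correlations=corrs,
        x_coef=x_coef,
        y_coef=y_coef,
        x_scores=x_scores,
        y_scores=y_scores,
        wilks=wilks,
        ridge=ridge,
    )


def _bartlett_wilks(corrs: np.ndarray, n: int, p: int, q: int) -> pd.DataFrame:
    """Bartlett's sequential chi-square test on Wilks' Λ per dimension."""
    d = len(corrs)
    rows = []
    for k in range(d):
        lam = float(np.prod(1.0 - corrs[k:] ** 2))
        df = (p - k) * (q - k)
        if df <= 0 or n - 1 <= (p + q + 1) / 2 or lam <= 0:
            rows.append({"wilks_lambda": lam, "chi2": np.nan, "df": df, "p": np.nan})
            continue
        chi2 = -(n - 1 - (p + q + 1) / 2.0) * np.log(lam)
        rows.append(
            {"wilks_lambda": lam, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}
        )
    return pd.DataFrame(rows, index=[f"CC{i+1}" for i in range(d)])
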