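"""Factorizations of the SNP-exposure association matrix.

Three transformers, all scikit-learn estimators operating on the p x K
matrix gamma-hat (rows = SNPs = samples, columns = exposures = features):

* :class:`PrincipalComponents` — plain SVD, gamma = U D V'.  Dense
  loadings; every exposure contributes to every component.
* :class:`ZouSparsePCA` — the elastic-net reformulation of PCA.
  Alternates (i) per-component elastic-net regressions against the Gram
  matrix for the sparse loadings and (ii) an SVD-based orthogonal update
  of the auxiliary basis, yielding loadings with exact zeros.
* :class:`SparseComponentAnalysis` — rotation toward sparsity.  The
  leading principal subspace is kept fixed (so its explained variance is
  exactly preserved) while an orthogonal rotation, fitted by alternating
  soft-thresholding and orthogonal-Procrustes steps, aligns the basis
  with a sparse pattern; thresholded entries are exact zeros.

Scores are always the uncentered projection ``gamma @ loadings`` — the
quantity substituted for gamma-hat in the second-step MR.  Eigenvalues are
reported on the scale of the uncentered matrix with unit-norm columns
(cross-product trace K, so a non-informative column contributes ~1), the
reference level the retention criteria assume.

Component signs are not identified; every loadings column is flipped so
its largest-magnitude entry is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import SnpExposureMatrix

__all__ = [
    "Decomposition",
    "SparseConfig",
    "PrincipalComponents",
    "ZouSparsePCA",
    "SparseComponentAnalysis",
    "pca",
    "spca_zou",
    "sca",
]


@dataclass
class SparseConfig:
    """Penalty and convergence settings for the Zou elastic-net sparse PCA.

    lambda1 is the L1 penalty driving exact zeros; lambda2 the ridge term
    that stabilizes the Gram system when K approaches p.  Alternatively a
    per-component cardinality cap selects the penalty adaptively so each
    component keeps at most that many nonzero loadings.
    """

    lambda1: float = 0.0
    lambda2: float = 1e-6
    per_component_cardinality: int | None = None
    n_components_requested: int = 2
    max_iter: int = 200
    tol: float = 1e-6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be nonnegative")
        if self.n_components_requested < 1:
            raise ValueError("need at least one component")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid iteration settings")
        if self.per_component_cardinality is not None and (
            self.per_component_cardinality < 1
        ):
            raise ValueError("cardinality must be >= 1")


@dataclass
class Decomposition:
    """Loadings/scores factorization of a SNP-exposure matrix."""

    method_label: str
    exposure_ids: list[str]
    loadings: np.ndarray  # K x m, unit-norm columns (zero columns allowed)
    scores: np.ndarray  # p x m, uncentered gamma @ loadings
    eigenvalues: np.ndarray  # m, eigenvalues on the unit-scaled-column scale
    explained_variance_fraction: np.ndarray
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def sparsity_fraction(self) -> float:
        return float(np.mean(self.loadings == 0.0))

    def component_ids(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]

    def loadings_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.loadings, index=self.exposure_ids, columns=self.component_ids()
        )


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        if np.any(col):
            if col[np.argmax(np.abs(col))] < 0:
                V[:, j] = -col
    return V


def _normalize_columns(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    norms = np.linalg.norm(V, axis=0)
    nz = norms > 0
    V[:, nz] /= norms[nz]
    return V


def _unit_scale(X: np.ndarray) -> np.ndarray:
    """Uncentered column scaling to unit norm (eigenvalue trace K)."""
    norms = np.linalg.norm(X, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    return X / norms


def _soft_threshold(a: np.ndarray, t: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - t, 0.0)


class PrincipalComponents(TransformerMixin, BaseEstimator):
    """Plain (uncentered) principal component analysis of gamma-hat.

    Attributes
    ----------
    components_ : ndarray of shape (m, K)
        Right singular vectors (rows), scikit-learn orientation.
    singular_values_ : ndarray of shape (m,)
        Singular values of the uncentered matrix.
    eigenvalues_ : ndarray of shape (m,)
        Leading eigenvalues of the cross-product of the unit-norm-scaled
        columns (trace K): the scale the retention criteria expect.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        p, k = X.shape
        m = self.n_components
        if not 1 <= m <= min(p, k):
            raise ValueError(f"n_components must be in [1, {min(p, k)}], got {m}")
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        V = _fix_signs(Vt[:m].T)
        self.n_features_in_ = k
        self.components_ = V.T
        self.singular_values_ = s[:m]
        self.all_singular_values_ = s
        Z = _unit_scale(X)
        scaled_eigs = np.linalg.svd(Z, compute_uv=False) ** 2
        self.eigenvalues_ = scaled_eigs[:m]
        self.explained_variance_ratio_ = self.eigenvalues_ / k
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.components_.T

    def component_eigenvalues(self, Z: np.ndarray) -> np.ndarray:
        """Eigenvalue spectrum of an externally unit-scaled matrix."""
        s = np.linalg.svd(Z, compute_uv=False)
        return (s**2)[: self.n_components]


class ZouSparsePCA(TransformerMixin, BaseEstimator):
    """Sparse PCA via the elastic-net regression formulation.

    With Gram matrix G = X'X, alternate until the loadings stabilize:

    1. for each component j, with the orthonormal basis A fixed, solve
       ``xi_j = argmin (a_j - xi)' G (a_j - xi) + lambda2 ||xi||^2
       + lambda1 ||xi||_1`` (coordinate descent); when a per-component
       cardinality cap is set instead, the ridge solution is
       soft-thresholded at the (cap+1)-th largest magnitude so at most
       ``cap`` loadings survive;
    2. with the sparse loadings Xi fixed, update A from the SVD of G Xi:
       ``G Xi = U D W'``, ``A = U W'``.

    Non-convergence at ``max_iter`` sets ``converged_ = False`` (a warning,
    not an error).  A component shrunk entirely to zero under an extreme
    lambda1 is retained as a zero column with a warning.
    """

    def __init__(
        self,
        n_components: int = 2,
        lambda1: float = 0.0,
        lambda2: float = 1e-6,
        cardinality: int | None = None,
        max_iter: int = 200,
        tol: float = 1e-6,
    ):
        self.n_components = n_components
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.cardinality = cardinality
        self.max_iter = max_iter
        self.tol = tol

    # -- elastic net on the Gram matrix -----------------------------------
    @staticmethod
    def _cd_elastic_net(M, b, lam1, xi0, n_sweeps=100, tol=1e-10):
        """Minimize xi' M xi - 2 b' xi + lam1 ||xi||_1 by coordinate descent."""
        xi = xi0.copy()
        d = np.diag(M)
        for _ in range(n_sweeps):
            delta = 0.0
            for i in range(len(b)):
                r = b[i] - M[i] @ xi + d[i] * xi[i]
                new = np.sign(r) * max(abs(r) - lam1 / 2.0, 0.0) / d[i]
                delta = max(delta, abs(new - xi[i]))
                xi[i] = new
            if delta < tol:
                break
        return xi

    def _xi_step(self, G, A, ridge_chol):
        K, m = A.shape
        B = G @ A
        if self.cardinality is not None and self.lambda1 == 0.0:
            import scipy.linalg as sla

            Xi = sla.cho_solve(ridge_chol, B)
            c = min(self.cardinality, K)
            for j in range(m):
                a = np.abs(Xi[:, j])
                if c < K:
                    # stable tie-break: order statistics on (-|xi|, column index)
                    order = np.lexsort((np.arange(K), -a))
                    t = a[order[c]]
                    Xi[:, j] = _soft_threshold(Xi[:, j], t)
                    # enforce the cap exactly under ties
                    nz = np.nonzero(Xi[:, j])[0]
                    if len(nz) > c:
                        drop = [i for i in order[c:] if Xi[i, j] != 0]
                        Xi[drop, j] = 0.0
            return Xi
        Xi = np.empty((K, m))
        M = G + self.lambda2 * np.eye(K)
        for j in range(m):
            Xi[:, j] = self._cd_elastic_net(M, B[:, j], self.lambda1, A[:, j].copy())
        return Xi

    def _objective(self, G, A, Xi):
        diff = A - Xi
        val = float(np.einsum("kj,kl,lj->", diff, G, diff))
        val += self.lambda2 * float(np.sum(Xi**2))
        val += self.lambda1 * float(np.sum(np.abs(Xi)))
        return val

    def fit(self, X, y=None):
        import scipy.linalg as sla

        X = np.asarray(X, dtype=float)
        p, K = X.shape
        m = self.n_components
        if not 1 <= m <= min(p, K):
            raise ValueError(f"n_components must be in [1, {min(p, K)}], got {m}")
        G = X.T @ X
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        A = Vt[:m].T
        ridge_chol = None
        if self.cardinality is not None and self.lambda1 == 0.0:
            ridge_chol = sla.cho_factor(G + self.lambda2 * np.eye(K))
        objective = []
        converged = False
        Xi = A.copy()
        for _ in range(self.max_iter):
            Xi_new = self._xi_step(G, A, ridge_chol)
            objective.append(self._objective(G, A, Xi_new))
            # SVD update of the orthonormal basis
            GXi = G @ Xi_new
            U, _, Wt = np.linalg.svd(GXi, full_matrices=False)
            A = U @ Wt
            if np.max(np.abs(Xi_new - Xi)) < self.tol * max(
                1.0, np.max(np.abs(Xi))
            ):
                Xi = Xi_new
                converged = True
                break
            Xi = Xi_new
        if not converged:
            warnings.warn("sparse PCA did not converge within max_iter")
        if np.any(np.linalg.norm(Xi, axis=0) == 0):
            warnings.warn("component(s) shrunk entirely to zero under lambda1")
        V = _fix_signs(_normalize_columns(Xi))
        self.n_features_in_ = K
        self.components_ = V.T
        self.converged_ = converged
        self.objective_path_ = np.asarray(objective)
        Z = _unit_scale(X)
        self.eigenvalues_ = self.component_eigenvalues(Z)
        self.explained_variance_ratio_ = self.eigenvalues_ / K
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.components_.T

    def component_eigenvalues(self, Z: np.ndarray) -> np.ndarray:
        V = self.components_.T
        lam = np.empty(V.shape[1])
        for j in range(V.shape[1]):
            v = V[:, j]
            n = np.linalg.norm(v)
            lam[j] = 0.0 if n == 0 else np.sum((Z @ (v / n)) ** 2)
        return lam


def _varimax(V: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation matrix R maximizing loading variance of V @ R."""
    K, m = V.shape
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        L = V @ R
        u, s, vt = np.linalg.svd(V.T @ (L**3 - L @ np.diag(np.mean(L**2, axis=0))))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d - d_old < tol * d_old:
            break
        d_old = d
    return R


class SparseComponentAnalysis(TransformerMixin, BaseEstimator):
    """Sparse components by rotating the leading principal subspace.

    Starting from the m leading principal loadings (optionally pre-rotated
    by varimax, which already concentrates loading mass), alternate

    1. soft-threshold the rotated loadings ``V R`` at ``threshold`` to get
       a sparse target T, and
    2. refit the orthogonal rotation by the Procrustes problem
       ``R = argmin ||V R - T||_F`` over orthogonal R,

    until the zero pattern stabilizes.  Because R is orthogonal, the m-
    dimensional subspace — and hence its total explained variance — is
    exactly that of plain PCA.  Reported loadings are the thresholded,
    renormalized columns (exact zeros where thresholded).

    ``threshold=None`` picks the largest threshold from a small grid such
    that the retained entries keep at least ``min_retained_norm`` of every
    rotated column's squared norm.
    """

    def __init__(
        self,
        n_components: int = 2,
        threshold: float | None = None,
        min_retained_norm: float = 0.95,
        varimax_init: bool = True,
        max_iter: int = 100,
    ):
        self.n_components = n_components
        self.threshold = threshold
        self.min_retained_norm = min_retained_norm
        self.varimax_init = varimax_init
        self.max_iter = max_iter

    def _auto_threshold(self, VR: np.ndarray) -> float:
        """Largest grid threshold whose surviving entries still carry at
        least ``min_retained_norm`` of every column's squared norm (the
        entries themselves are judged unshrunk; only the zero pattern
        matters for this accounting)."""
        flat = np.abs(VR).ravel()
        grid = np.unique(np.quantile(flat, np.linspace(0.0, 0.95, 20)))
        orig = np.sum(VR**2, axis=0)
        best = 0.0
        for t in grid:
            mask = np.abs(VR) > t
            kept = np.where(orig > 0, np.sum(VR**2 * mask, axis=0) / orig, 1.0)
            if np.all(kept >= self.min_retained_norm):
                best = max(best, float(t))
        return best

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        p, K = X.shape
        m = self.n_components
        if not 1 <= m <= min(p, K):
            raise ValueError(f"n_components must be in [1, {min(p, K)}], got {m}")
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        V = Vt[:m].T  # orthonormal basis of the leading subspace
        R = _varimax(V) if self.varimax_init and m > 1 else np.eye(m)
        t = self.threshold
        if t is None:
            t = self._auto_threshold(V @ R)
        pattern = None
        for _ in range(self.max_iter):
            VR = V @ R
            T = _soft_threshold(VR, t)
            new_pattern = T != 0
            if not np.any(new_pattern):
                raise ValueError("threshold too large: all loadings vanish")
            if pattern is not None and np.array_equal(new_pattern, pattern):
                break
            pattern = new_pattern
            U, _, Wt = np.linalg.svd(V.T @ T, full_matrices=False)
            R = U @ Wt
        loadings = _fix_signs(_normalize_columns(T))
        self.n_features_in_ = K
        self.components_ = loadings.T
        self.rotation_ = R
        self.threshold_ = float(t)
        self.subspace_basis_ = V @ R
        # explained variance of the (rotation-invariant) m-subspace
        self.subspace_variance_ = float(np.sum(s[:m] ** 2))
        Z = _unit_scale(X)
        self.eigenvalues_ = self.component_eigenvalues(Z)
        self.explained_variance_ratio_ = self.eigenvalues_ / K
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.components_.T

    def component_eigenvalues(self, Z: np.ndarray) -> np.ndarray:
        V = self.components_.T
        lam = np.empty(V.shape[1])
        for j in range(V.shape[1]):
            v = V[:, j]
            n = np.linalg.norm(v)
            lam[j] = 0.0 if n == 0 else np.sum((Z @ (v / n)) ** 2)
        return lam


# ---------------------------------------------------------------------------
# functional wrappers returning Decomposition objects


def _decomposition_from(est, exposures: SnpExposureMatrix, label: str) -> Decomposition:
    V = est.components_.T
    scores = exposures.gamma @ V
    return Decomposition(
        method_label=label,
        exposure_ids=list(exposures.exposure_ids),
        loadings=V,
        scores=scores,
        eigenvalues=np.asarray(est.eigenvalues_, dtype=float),
        explained_variance_fraction=np.asarray(
            est.explained_variance_ratio_, dtype=float
        ),
        converged=getattr(est, "converged_", True),
    )


def pca(exposures: SnpExposureMatrix, m: int) -> Decomposition:
    """Plain PCA of the uncentered gamma-hat matrix."""
    est = PrincipalComponents(n_components=m).fit(exposures.gamma)
    return _decomposition_from(est, exposures, "PCA")


def spca_zou(exposures: SnpExposureMatrix, config: SparseConfig) -> Decomposition:
    """Elastic-net sparse PCA (alternating regression / SVD updates)."""
    est = ZouSparsePCA(
        n_components=config.n_components_requested,
        lambda1=config.lambda1,
        lambda2=config.lambda2,
        cardinality=config.per_component_cardinality,
        max_iter=config.max_iter,
        tol=config.tol,
    ).fit(exposures.gamma)
    return _decomposition_from(est, exposures, "SPCA_ZOU")


def sca(
    exposures: SnpExposureMatrix, m: int, threshold: float | None = None
) -> Decomposition:
    """Rotation-based sparse component analysis."""
    est = SparseComponentAnalysis(n_components=m, threshold=threshold).fit(
        exposures.gamma
    )
    return _decomposition_from(est, exposures, "SCA")
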