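"""Data-driven choice of informative components and their instrument strength.

Two retention rules:

* **Permutation.**  Each column of the unit-norm-scaled gamma-hat matrix
  is shuffled independently and entry signs are randomized (under the null
  of a non-informative component the association estimates carry no
  systematic sign, and keeping the shared positive column means would
  leak real structure into the null), the decomposition is re-fitted, and
  its eigenvalues are taken as draws from the null spectrum.  Component k
  is informative when its observed eigenvalue exceeds the k-th null
  reference — by default the 0.95 null quantile; the retained count is
  the leading run of informative components.  A mean-comparison variant
  (``null_reference="mean"``) and a shuffle without sign flips
  (``scheme="columns-noflip"``) are available; both are liberal: under
  pure noise the observed spectrum is itself a draw from the permutation
  distribution, so a mean comparison turns every rank into a coin flip.
* **KSS.**  A corrected minimum-eigenvalue rule: retain components whose
  eigenvalue (on the trace-K scale above, where a non-informative column
  contributes ~1) exceeds ``1 + 2 * sqrt((K - 1) / (p - 1))``.

Instrument strength of a component with loading vector v is measured by
propagating the per-SNP exposure standard errors through the projection:
the component score for SNP j is ``gamma_j . v`` with delta-method variance
``v' diag(se_j^2) v`` (cross-exposure covariances taken as zero), and

    F = (1/p) sum_j (gamma_j . v)^2 / (v' diag(se_j^2) v),

the single-exposure mean F-statistic applied to the transformed exposure.
This is the form consistent with treating the MVMR fit on (near-)orthogonal
component scores as a set of per-component univariable analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AnalysisConfig, SnpExposureMatrix
from .decomposition import (
    PrincipalComponents,
    SparseComponentAnalysis,
    ZouSparsePCA,
)

__all__ = [
    "RetentionResult",
    "PcStrength",
    "permutation_retention",
    "kss_retention",
    "kss_cutoff",
    "pc_f_statistic",
]


@dataclass
class RetentionResult:
    method_label: str  # "PERMUTATION" or "KSS"
    n_retained: int
    retained: np.ndarray  # boolean mask over evaluated components
    observed_eigenvalues: np.ndarray
    null_mean_eigenvalues: np.ndarray | None = None
    cutoff: float | None = None
    n_permutations: int = 0


@dataclass
class PcStrength:
    component_ids: list[str]
    f_statistics: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"component": self.component_ids, "F": self.f_statistics}
        )


def _make_estimator(method: str, m: int, **kwargs):
    method = method.lower()
    if method == "pca":
        return PrincipalComponents(n_components=m)
    if method in ("spca", "spca_zou"):
        return ZouSparsePCA(n_components=m, **kwargs)
    if method == "sca":
        return SparseComponentAnalysis(n_components=m, **kwargs)
    raise ValueError(f"unknown reduction method {method!r}")


def _permute(Z: np.ndarray, rng: np.random.Generator, scheme: str) -> np.ndarray:
    if scheme in ("columns", "columns-noflip"):
        out = np.empty_like(Z)
        for k in range(Z.shape[1]):
            out[:, k] = rng.permutation(Z[:, k])
        if scheme == "columns":
            out *= rng.choice([-1.0, 1.0], size=Z.shape)
        return out
    if scheme == "rows":
        return Z[rng.permutation(Z.shape[0])]
    if scheme == "entries":
        flat = rng.permutation(Z.ravel())
        return flat.reshape(Z.shape)
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_retention(
    exposures: SnpExposureMatrix,
    method: str = "pca",
    config: AnalysisConfig | None = None,
    m: int | None = None,
    scheme: str = "columns",
    null_reference: str = "quantile",
    quantile: float = 0.95,
    **method_kwargs,
) -> RetentionResult:
    """Permutation test for the number of informative components.

    Parameters
    ----------
    method : {"pca", "spca", "sca"}
        Reduction whose eigenvalue spectrum is compared to its permuted null.
    m : int, optional
        Number of candidate components evaluated (default ``min(p, K)``).
    scheme : {"columns", "columns-noflip", "rows", "entries"}
        What is randomized per permutation; independent within-column
        shuffles with sign randomization are the default.
    null_reference : {"quantile", "mean"}
        Per-rank null summary the observed eigenvalue must exceed.
    quantile : float
        Null quantile used when ``null_reference="quantile"``.

    Notes
    -----
    ``n_retained`` is the length of the leading run of components whose
    observed eigenvalue exceeds its null reference; the full per-rank mask
    is reported in ``retained``.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.rng_seed)
    Z = exposures.unit_scaled()
    p, K = Z.shape
    if m is None:
        m = min(p, K)
    est = _make_estimator(method, m, **method_kwargs)
    observed = est.fit(Z).component_eigenvalues(Z)

    null = np.empty((config.n_permutations, m))
    for b in range(config.n_permutations):
        Zp = _permute(Z, rng, scheme)
        eb = _make_estimator(method, m, **method_kwargs)
        null[b] = eb.fit(Zp).component_eigenvalues(Zp)
    if null_reference == "mean":
        reference = null.mean(axis=0)
    elif null_reference == "quantile":
        reference = np.quantile(null, quantile, axis=0)
    else:
        raise ValueError(f"unknown null_reference {null_reference!r}")
    exceeds = observed > reference
    n_leading = int(np.argmin(exceeds)) if not exceeds.all() else int(m)
    return RetentionResult(
        method_label="PERMUTATION",
        n_retained=n_leading,
        retained=exceeds,
        observed_eigenvalues=observed,
        null_mean_eigenvalues=reference,
        n_permutations=config.n_permutations,
    )


def kss_cutoff(K: int, p: int) -> float:
    """Corrected eigenvalue cutoff 1 + 2 sqrt((K - 1) / (p - 1))."""
    if p <= 1:
        raise ValueError("cutoff undefined for p <= 1")
    if K <= 1:
        raise ValueError("cutoff undefined for K <= 1")
    return 1.0 + 2.0 * np.sqrt((K - 1) / (p - 1))


def kss_retention(eigenvalues, K: int, p: int) -> RetentionResult:
    """Retain components whose (trace-K scale) eigenvalue exceeds the cutoff."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    cutoff = kss_cutoff(K, p)
    retained = eigenvalues > cutoff
    return RetentionResult(
        method_label="KSS",
        n_retained=int(retained.sum()),
        retained=retained,
        observed_eigenvalues=eigenvalues,
        cutoff=cutoff,
    )


def pc_f_statistic(exposures: SnpExposureMatrix, loadings) -> PcStrength:
    """Delta-method instrument-strength F-statistic per component.

    ``loadings`` is K x m; columns must be nonzero.  Scale-invariant in each
    loading column.
    """
    V = np.atleast_2d(np.asarray(loadings, dtype=float))
    if V.shape[0] != exposures.n_exposures:
        raise ValueError("loadings rows must match the number of exposures")
    norms = np.linalg.norm(V, axis=0)
    if np.any(norms == 0):
        raise ValueError("loadings columns must be nonzero")
    scores = exposures.gamma @ V  # p x m
    var = (exposures.se**2) @ (V**2)  # p x m, v' diag(se^2) v
    if np.any(var <= 0):
        raise ValueError("zero propagated variance for at least one SNP")
    f = np.mean(scores**2 / var, axis=0)
    ids = [f"PC{i + 1}" for i in range(V.shape[1])]
    return PcStrength(ids, f)
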