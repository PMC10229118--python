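"""End-to-end workflow: reduce gamma-hat, retain components, assess
strength, and run the second-step IVW MVMR on component scores.

The outcome associations are never transformed: the retained component
scores simply replace gamma-hat as the design matrix of the IVW
regression, with the original outcome standard errors as weights.
Component-level significance is judged at ``alpha / B`` where B is the
number of retained components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
from sklearn.base import BaseEstimator

from .data import AnalysisConfig, OutcomeStats, SnpExposureMatrix
from .decomposition import (
    Decomposition,
    PrincipalComponents,
    SparseConfig,
    pca,
    sca,
    spca_zou,
)
from .mr import IVWRegression, MrFit
from .selection import (
    PcStrength,
    RetentionResult,
    kss_retention,
    pc_f_statistic,
    permutation_retention,
)

__all__ = ["PipelineResult", "PcMrPipeline", "run_pipeline"]

#: candidate components evaluated when the caller does not fix m; real
#: applications of this workflow retain a handful of components, so a
#: cap keeps the permutation null affordable without constraining the answer
DEFAULT_MAX_COMPONENTS = 12


@dataclass
class PipelineResult:
    decomposition: Decomposition
    retention: RetentionResult
    strength: PcStrength | None
    mr_fit: MrFit
    alpha_corrected: float
    retained_indices: np.ndarray
    provenance: dict

    @property
    def n_retained(self) -> int:
        return int(self.retention.n_retained)

    @property
    def retained_loadings(self) -> np.ndarray:
        return self.decomposition.loadings[:, self.retained_indices]

    def significant(self) -> np.ndarray:
        """Boolean per retained component at the alpha/B level."""
        return np.asarray(self.mr_fit.p_values) < self.alpha_corrected


class PcMrPipeline(BaseEstimator):
    """scikit-learn-style wrapper around the four-step workflow.

    Parameters
    ----------
    method : {"pca", "spca", "sca"}
        Reduction applied to the SNP-exposure matrix.
    retention : {"permutation", "kss", "fixed"}
        How the number of informative components is chosen; "fixed" keeps
        the leading ``n_components`` as given.
    n_components : int, optional
        Candidate components (cap for data-driven retention, exact count
        for "fixed").
    cardinality : int, optional
        Per-component nonzero-loading cap for "spca".  When omitted it is
        set data-adaptively to ``ceil(K / m0)`` with m0 the component count
        a plain-PCA permutation test retains — mirroring how the sparsity
        level is chosen in applications of this workflow.
    threshold : float, optional
        Soft-threshold for "sca" (None: automatic grid choice).
    """

    def __init__(
        self,
        method: str = "pca",
        retention: str = "permutation",
        n_components: int | None = None,
        alpha: float = 0.05,
        n_permutations: int = 100,
        lambda1: float = 0.0,
        lambda2: float = 1e-6,
        cardinality: int | None = None,
        threshold: float | None = None,
        random_state: int = 0,
    ):
        self.method = method
        self.retention = retention
        self.n_components = n_components
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.cardinality = cardinality
        self.threshold = threshold
        self.random_state = random_state

    # -- internals --------------------------------------------------------
    def _decompose(
        self, exposures: SnpExposureMatrix, m: int, cardinality: int | None
    ) -> Decomposition:
        if self.method == "pca":
            return pca(exposures, m)
        if self.method in ("spca", "spca_zou"):
            cfg = SparseConfig(
                lambda1=self.lambda1,
                lambda2=self.lambda2,
                per_component_cardinality=cardinality,
                n_components_requested=m,
                rng_seed=self.random_state,
            )
            return spca_zou(exposures, cfg)
        if self.method == "sca":
            return sca(exposures, m, threshold=self.threshold)
        raise ValueError(f"unknown reduction method {self.method!r}")

    def _method_kwargs(self, cardinality: int | None) -> dict:
        if self.method in ("spca", "spca_zou"):
            return {
                "lambda1": self.lambda1,
                "lambda2": self.lambda2,
                "cardinality": cardinality,
            }
        if self.method == "sca":
            return {"threshold": self.threshold}
        return {}

    def fit(self, exposures: SnpExposureMatrix, outcome: OutcomeStats):
        if list(exposures.snp_ids) != list(outcome.snp_ids):
            raise ValueError("exposure and outcome tables are not aligned")
        p, K = exposures.n_snps, exposures.n_exposures
        m_max = self.n_components or min(p, K, DEFAULT_MAX_COMPONENTS)
        m_max = min(m_max, p, K)
        config = AnalysisConfig(
            alpha=self.alpha,
            n_permutations=max(self.n_permutations, 1),
            rng_seed=self.random_state,
        )

        # Step 1: how many informative components?  Decided on the principal
        # eigenvalue spectrum (sparse rotations live in the same subspace),
        # then the chosen reduction is fitted with that many components.
        if self.retention == "permutation":
            retention = permutation_retention(
                exposures, method="pca", config=config, m=m_max
            )
        elif self.retention == "kss":
            spectrum = PrincipalComponents(n_components=m_max).fit(
                exposures.gamma
            ).eigenvalues_
            retention = kss_retention(spectrum, K, p)
        elif self.retention == "fixed":
            retention = RetentionResult(
                method_label="FIXED",
                n_retained=m_max,
                retained=np.ones(m_max, dtype=bool),
                observed_eigenvalues=np.full(m_max, np.nan),
            )
        else:
            raise ValueError(f"unknown retention rule {self.retention!r}")

        b = int(retention.n_retained)
        alpha_corrected = self.alpha / max(b, 1)
        cardinality = self.cardinality

        if b == 0:
            warnings.warn("no components retained; returning empty MR fit")
            decomp = self._decompose(exposures, 1, cardinality)
            retained_idx = np.array([], dtype=int)
            strength = None
            mr_fit = MrFit([], np.array([]), np.array([]), np.array([]), "MVMR-PC")
        else:
            if self.method in ("spca", "spca_zou") and cardinality is None and (
                self.lambda1 == 0.0
            ):
                cardinality = ceil(K / b)
            decomp = self._decompose(exposures, b, cardinality)
            # sparse fits can shrink a whole component to zero; drop those
            retained_idx = np.array(
                [i for i in range(b) if np.any(decomp.loadings[:, i])], dtype=int
            )
            b = len(retained_idx)
            alpha_corrected = self.alpha / max(b, 1)
        if b > 0:
            V = decomp.loadings[:, retained_idx]
            strength = pc_f_statistic(exposures, V)
            scores = decomp.scores[:, retained_idx]
            est = IVWRegression().fit(scores, outcome.Gamma, outcome_se=outcome.se)
            ids = [f"PC{i + 1}" for i in retained_idx]
            mr_fit = est.to_mrfit(ids, "MVMR-PC")

        self.result_ = PipelineResult(
            decomposition=decomp,
            retention=retention,
            strength=strength,
            mr_fit=mr_fit,
            alpha_corrected=alpha_corrected,
            retained_indices=retained_idx,
            provenance={
                "method": self.method,
                "retention": self.retention,
                "n_candidates": int(m_max),
                "alpha": self.alpha,
                "n_permutations": self.n_permutations,
                "cardinality": cardinality,
                "threshold": self.threshold,
                "lambda1": self.lambda1,
                "lambda2": self.lambda2,
                "random_state": self.random_state,
            },
        )
        return self


def run_pipeline(
    exposures: SnpExposureMatrix,
    outcome: OutcomeStats,
    method: str = "pca",
    config: AnalysisConfig | None = None,
    sparse_config: SparseConfig | None = None,
    retention: str = "permutation",
    n_components: int | None = None,
    threshold: float | None = None,
) -> PipelineResult:
    """Functional facade over :class:`PcMrPipeline`."""
    config = config or AnalysisConfig()
    kwargs: dict = {}
    if sparse_config is not None:
        kwargs.update(
            lambda1=sparse_config.lambda1,
            lambda2=sparse_config.lambda2,
            cardinality=sparse_config.per_component_cardinality,
        )
        if n_components is None:
            n_components = sparse_config.n_components_requested
    est = PcMrPipeline(
        method=method,
        retention=retention,
        n_components=n_components,
        alpha=config.alpha,
        n_permutations=config.n_permutations,
        threshold=threshold,
        random_state=config.rng_seed,
        **kwargs,
    ).fit(exposures, outcome)
    return est.result_
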