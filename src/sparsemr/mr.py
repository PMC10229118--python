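"""Inverse-variance-weighted univariable and multivariable MR.

The causal effect vector beta minimises the weighted residual sum of
squares

    Q_A = sum_j (Gamma_j - sum_k beta_k gamma_jk)^2 / sigma2_Aj,

with the simplifying working model sigma2_Aj = sigma2_Yj (the NOME
assumption: SNP-exposure estimates treated as known).  This is weighted
least squares of the SNP-outcome estimates on the SNP-exposure estimates
through the origin, with weights 1/sigma2_Yj.  The full variance model,
adding per-exposure measurement error and optional cross-exposure
covariances, is available for evaluating Q_A at the fitted beta.

Instrument-strength diagnostics:

* mean F-statistic per exposure, F_k = (1/p) sum_j (gamma_jk / se_jk)^2;
* conditional F-statistic CFS_k = Q_Xk / (p - (K-1)), where Q_Xk is the
  weighted heterogeneity left in exposure k's SNP associations after an
  origin-through OLS regression on all other exposures' associations.
  CFS is small exactly when an exposure is predictable from the others —
  the conditionally-weak-instrument regime that motivates moving to
  component scores.

Inference is Wald-type with normal quantiles, the summary-data MR
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .data import SnpExposureMatrix

__all__ = [
    "MrFit",
    "QStatistic",
    "InstrumentStrength",
    "IVWRegression",
    "ivw_uvmr",
    "ivw_mvmr",
    "q_a_statistic",
    "mean_f",
    "conditional_f",
    "instrument_strength",
]

_RANK_RTOL = 1e-10  # relative condition threshold for collinearity failure


@dataclass
class QStatistic:
    """Heterogeneity statistic Q_A with its per-SNP decomposition."""

    value: float
    dof: int
    per_snp_contributions: np.ndarray
    variance_model: str  # "simple" or "full"


@dataclass
class MrFit:
    """Per-predictor causal estimates from an IVW fit."""

    predictor_ids: list[str]
    beta_hat: np.ndarray
    se_beta: np.ndarray
    p_values: np.ndarray
    method_label: str
    q_statistic: QStatistic | None = None

    @property
    def odds_ratios(self) -> np.ndarray:
        """exp(beta); meaningful when the outcome is on the log-odds scale."""
        return np.exp(self.beta_hat)

    def odds_ratio_ci(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.beta_hat - z * self.se_beta)
        hi = np.exp(self.beta_hat + z * self.se_beta)
        return np.column_stack([lo, hi])

    def to_frame(self):
        import pandas as pd

        ci = self.odds_ratio_ci()
        return pd.DataFrame(
            {
                "predictor": self.predictor_ids,
                "beta": self.beta_hat,
                "se": self.se_beta,
                "p": self.p_values,
                "OR": self.odds_ratios,
                "CI_low": ci[:, 0],
                "CI_high": ci[:, 1],
            }
        )


@dataclass
class InstrumentStrength:
    """Per-exposure strength diagnostics for an MVMR design."""

    exposure_ids: list[str]
    mean_f: np.ndarray
    conditional_f: np.ndarray
    q_x: np.ndarray
    delta_coefficients: list[np.ndarray] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "exposure": self.exposure_ids,
                "mean_F": self.mean_f,
                "CFS": self.conditional_f,
                "Q_X": self.q_x,
            }
        )


class IVWRegression(RegressorMixin, BaseEstimator):
    """Inverse-variance-weighted regression through the origin.

    scikit-learn-style estimator: ``fit(X, y, outcome_se=...)`` where X is
    the p x K matrix of SNP-exposure associations (or component scores) and
    y the p-vector of SNP-outcome associations.  Weights are 1/outcome_se^2.

    Attributes
    ----------
    coef_ : ndarray of shape (K,)
        Estimated causal effects.
    se_ : ndarray of shape (K,)
        Standard errors from the weighted information matrix.
    pvalues_ : ndarray of shape (K,)
        Two-sided normal (Wald) p-values.
    q_ : float
        Residual heterogeneity statistic under the simple variance model.
    q_dof_ : int
        p - K.
    """

    def __init__(self, check_rank: bool = True):
        self.check_rank = check_rank

    def fit(self, X, y, outcome_se=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim == 2 and X.shape[0] == 1 and np.asarray(y).size > 1:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        p, k = X.shape
        if y.shape[0] != p:
            raise ValueError("X and y have incompatible shapes")
        if p <= k and k > 1:
            raise ValueError(f"need more SNPs than predictors (p={p}, K={k})")
        if p < 2:
            raise ValueError("need at least 2 SNPs")
        if outcome_se is None:
            outcome_se = np.ones(p)
        outcome_se = np.asarray(outcome_se, dtype=float).ravel()
        if np.any(outcome_se <= 0):
            raise ValueError("outcome standard errors must be positive")
        if not np.any(X):
            raise ValueError("no instrument signal: all SNP-exposure estimates zero")

        w = 1.0 / outcome_se**2
        Xw = X * np.sqrt(w)[:, None]
        yw = y * np.sqrt(w)
        if self.check_rank:
            sv = np.linalg.svd(Xw, compute_uv=False)
            if sv[0] == 0 or sv[-1] / sv[0] < _RANK_RTOL:
                bad = _collinear_columns(Xw)
                raise ValueError(
                    "SNP-exposure matrix is rank deficient (multicollinear "
                    f"exposures); offending columns {bad}"
                )
        xtx = Xw.T @ Xw
        coef = np.linalg.solve(xtx, Xw.T @ yw)
        cov = np.linalg.inv(xtx)
        resid = yw - Xw @ coef
        self.n_features_in_ = k
        self.coef_ = coef
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.pvalues_ = 2 * stats.norm.sf(np.abs(coef / self.se_))
        self.q_contributions_ = resid**2
        self.q_ = float(resid @ resid)
        self.q_dof_ = p - k
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_

    def to_mrfit(self, predictor_ids=None, label=None) -> MrFit:
        k = self.coef_.shape[0]
        if predictor_ids is None:
            predictor_ids = [f"x{i + 1}" for i in range(k)]
        if label is None:
            label = "UVMR" if k == 1 else "MVMR"
        q = QStatistic(self.q_, self.q_dof_, self.q_contributions_, "simple")
        return MrFit(list(predictor_ids), self.coef_, self.se_, self.pvalues_, label, q)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Columns implicated in the rank deficiency (smallest right singular vector)."""
    _, _, vt = np.linalg.svd(X)
    v = np.abs(vt[-1])
    return sorted(np.nonzero(v > 0.5 * v.max())[0].tolist())


def ivw_uvmr(gamma, Gamma, se_Gamma, predictor_id: str = "exposure") -> MrFit:
    """Univariable IVW MR: single-exposure weighted least squares through 0."""
    gamma = np.asarray(gamma, dtype=float).ravel()
    est = IVWRegression().fit(gamma[:, None], Gamma, outcome_se=se_Gamma)
    return est.to_mrfit([predictor_id], "UVMR")


def ivw_mvmr(gamma, Gamma, se_Gamma, predictor_ids=None) -> MrFit:
    """Multivariable IVW MR of Gamma-hat on the columns of gamma-hat.

    Raises a hard error when the exposure matrix is (numerically) rank
    deficient — the multicollinear failure mode this package exists to
    route around.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    est = IVWRegression().fit(gamma, Gamma, outcome_se=se_Gamma)
    label = "UVMR" if gamma.shape[1] == 1 else "MVMR"
    return est.to_mrfit(predictor_ids, label)


def q_a_statistic(
    fit: MrFit,
    gamma,
    se_gamma,
    Gamma,
    se_Gamma,
    covariances=None,
) -> QStatistic:
    """Evaluate Q_A at the fitted beta under the full variance model.

    sigma2_Aj = sigma2_Yj + sum_k beta_k^2 sigma2_kj
              + sum_{l != k} 2 beta_l beta_k sigma_lkj,

    with the cross-exposure covariance terms sigma_lkj taken as zero unless
    per-SNP K x K covariance matrices are supplied.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    se_gamma = np.atleast_2d(np.asarray(se_gamma, dtype=float))
    Gamma = np.asarray(Gamma, dtype=float).ravel()
    se_Gamma = np.asarray(se_Gamma, dtype=float).ravel()
    beta = np.asarray(fit.beta_hat, dtype=float).ravel()
    p, k = gamma.shape
    if beta.shape[0] != k:
        raise ValueError("fit dimension does not match gamma")

    var = se_Gamma**2 + (se_gamma**2) @ beta**2
    if covariances is not None:
        covariances = np.asarray(covariances, dtype=float)
        if covariances.shape != (p, k, k):
            raise ValueError("covariances must have shape (p, K, K)")
        # quadratic form beta' Sigma_j beta minus the diagonal part already
        # counted through se_gamma
        quad = np.einsum("k,jkl,l->j", beta, covariances, beta)
        diag = np.einsum("jkk,k->j", covariances, beta**2)
        var = se_Gamma**2 + (se_gamma**2) @ beta**2 + (quad - diag)
    if np.any(var <= 0):
        raise ValueError("non-positive sigma2_Aj: invalid covariance input")
    resid = Gamma - gamma @ beta
    contrib = resid**2 / var
    return QStatistic(float(contrib.sum()), p - k, contrib, "full")


def mean_f(gamma, se_gamma) -> float:
    """Mean F-statistic of one exposure: (1/p) sum_j (gamma_j / se_j)^2."""
    gamma = np.asarray(gamma, dtype=float).ravel()
    se_gamma = np.asarray(se_gamma, dtype=float).ravel()
    if np.any(se_gamma <= 0):
        raise ValueError("standard errors must be positive")
    return float(np.mean((gamma / se_gamma) ** 2))


def conditional_f(
    exposures: SnpExposureMatrix, k: int, covariances=None
) -> tuple[float, float, np.ndarray]:
    """Conditional F-statistic of exposure ``k`` given all other exposures.

    Regresses column k of gamma-hat on the remaining columns by OLS with no
    intercept, then measures the weighted heterogeneity of the residuals:

        Q_Xk = sum_j (gamma_kj - sum_m delta_m gamma_mj)^2 / sigma2_Xkj,
        sigma2_Xkj = sigma2_kj + sum_m delta_m^2 sigma2_mj (+ covariances),
        CFS_k = Q_Xk / (p - (K - 1)).

    Returns ``(cfs, q_x, delta)``.
    """
    g, s = exposures.gamma, exposures.se
    p, K = g.shape
    if K < 2:
        raise ValueError("conditional F requires at least two exposures")
    if p - (K - 1) <= 0:
        raise ValueError(f"CFS undefined: p - (K-1) = {p - (K - 1)} <= 0")
    others = [m for m in range(K) if m != k]
    Xo = g[:, others]
    sv = np.linalg.svd(Xo, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < _RANK_RTOL:
        raise ValueError("remaining exposure columns are perfectly collinear")
    delta, *_ = np.linalg.lstsq(Xo, g[:, k], rcond=None)
    resid = g[:, k] - Xo @ delta
    var = s[:, k] ** 2 + (s[:, others] ** 2) @ delta**2
    if covariances is not None:
        covariances = np.asarray(covariances, dtype=float)
        sub = covariances[np.ix_(range(p), others, others)]
        quad = np.einsum("m,jml,l->j", delta, sub, delta)
        diag = np.einsum("jmm,m->j", sub, delta**2)
        var = var + (quad - diag)
    if np.any(var <= 0):
        raise ValueError("non-positive residual variance: invalid covariance input")
    q_x = float(np.sum(resid**2 / var))
    cfs = q_x / (p - (K - 1))
    return cfs, q_x, delta


def instrument_strength(
    exposures: SnpExposureMatrix, covariances=None
) -> InstrumentStrength:
    """Mean F and conditional F for every exposure of an MVMR design."""
    K = exposures.n_exposures
    mf = np.array(
        [mean_f(exposures.gamma[:, k], exposures.se[:, k]) for k in range(K)]
    )
    if K >= 2 and exposures.n_snps - (K - 1) > 0:
        out = [conditional_f(exposures, k, covariances) for k in range(K)]
        cfs = np.array([o[0] for o in out])
        qx = np.array([o[1] for o in out])
        deltas = [o[2] for o in out]
    else:
        warnings.warn("conditional F undefined for this design; reporting NaN")
        cfs = np.full(K, np.nan)
        qx = np.full(K, np.nan)
        deltas = []
    return InstrumentStrength(list(exposures.exposure_ids), mf, cfs, qx, deltas)
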