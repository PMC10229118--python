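"""Scoring method output against simulation truth and meta-analytic ROC.

Classification rule (component methods): an exposure is a *major
contributor* to a component iff its absolute loading exceeds the mean
absolute loading of that component's column (mean over all K entries,
zeros included).  An exposure is called positive iff it is a major
contributor to at least one component whose causal estimate is significant
at the corrected level.  For plain MVMR an exposure is called positive iff
its own Wald test is significant.  Calls crossed with the true causal
flags give TP/FP/TN/FN; sensitivity SNS = TP/(TP+FN), specificity
SPC = TN/(TN+FP), Youden's J = SNS + SPC - 1.

Across simulation settings the (SNS, SPC) pairs are pooled by a bivariate
random-effects meta-analysis on the logit scale (the summary-ROC approach
used for diagnostic test accuracy): within-setting binomial-approximation
variances plus an unstructured between-setting covariance, fitted by
maximum likelihood.  The summary ROC curve is traced from the fitted
bivariate relation and its AUC integrated over the full false-positive
range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .mr import MrFit
from .pipeline import PipelineResult

__all__ = [
    "ClassificationResult",
    "EvaluationSummary",
    "SrocSummary",
    "classify_calls",
    "merge_classifications",
    "summarize",
    "sroc_auc",
]


@dataclass
class ClassificationResult:
    method_label: str
    tp: int
    fp: int
    tn: int
    fn: int
    per_exposure_calls: dict[str, str]

    @property
    def n_exposures(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sns(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def spc(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def youden_j(self) -> float:
        return self.sns + self.spc - 1.0


def major_contributors(loadings: np.ndarray) -> np.ndarray:
    """Boolean K x m mask: |loading| above the column mean of |loadings|.

    Invariant to sign flips and to rescaling any column.
    """
    a = np.abs(np.atleast_2d(loadings))
    return a > a.mean(axis=0, keepdims=True)


def classify_calls(
    result: PipelineResult | MrFit,
    truth,
    alpha_corrected: float | None = None,
    method_label: str | None = None,
) -> ClassificationResult:
    """Cross positive/negative calls with the true causal flags.

    ``result`` is either a fitted pipeline (component method: the
    major-contributor rule at the pipeline's alpha/B level) or a raw-
    exposure MrFit (per-exposure Wald calls at ``alpha_corrected``).
    """
    truth = np.asarray(truth, dtype=bool)
    K = truth.shape[0]

    if isinstance(result, PipelineResult):
        alpha = (
            alpha_corrected if alpha_corrected is not None else result.alpha_corrected
        )
        label = method_label or result.decomposition.method_label
        positive = np.zeros(K, dtype=bool)
        if result.n_retained > 0:
            V = result.retained_loadings
            sig = np.asarray(result.mr_fit.p_values) < alpha
            contrib = major_contributors(V)
            positive = np.any(contrib[:, sig], axis=1)
        exposure_ids = result.decomposition.exposure_ids
    elif isinstance(result, MrFit):
        if alpha_corrected is None:
            raise ValueError("alpha_corrected is required for per-exposure calls")
        label = method_label or result.method_label
        positive = np.asarray(result.p_values) < alpha_corrected
        exposure_ids = result.predictor_ids
    else:
        raise TypeError("result must be a PipelineResult or MrFit")
    if len(exposure_ids) != K:
        raise ValueError("truth length does not match the number of exposures")

    calls = {}
    tp = fp = tn = fn = 0
    for k, name in enumerate(exposure_ids):
        if truth[k] and positive[k]:
            calls[name] = "TP"
            tp += 1
        elif truth[k]:
            calls[name] = "FN"
            fn += 1
        elif positive[k]:
            calls[name] = "FP"
            fp += 1
        else:
            calls[name] = "TN"
            tn += 1
    return ClassificationResult(label, tp, fp, tn, fn, calls)


def merge_classifications(results: list[ClassificationResult]) -> ClassificationResult:
    """Pool counts across replicates of one simulation setting."""
    if not results:
        raise ValueError("nothing to merge")
    return ClassificationResult(
        results[0].method_label,
        sum(r.tp for r in results),
        sum(r.fp for r in results),
        sum(r.tn for r in results),
        sum(r.fn for r in results),
        {},
    )


@dataclass
class EvaluationSummary:
    per_setting: "object"  # DataFrame: sns, spc, j per setting
    median_sns: float
    median_spc: float
    median_j: float
    iqr_sns: tuple[float, float]
    iqr_spc: tuple[float, float]


def summarize(results: list[ClassificationResult]) -> EvaluationSummary:
    """Per-setting SNS/SPC/J with medians and interquartile ranges.

    Undefined ratios (zero denominators) are recorded as missing and
    excluded from the medians, never coerced to zero.
    """
    import pandas as pd

    if not results:
        raise ValueError("no classification results to summarize")
    rows = [
        {
            "method": r.method_label,
            "tp": r.tp,
            "fp": r.fp,
            "tn": r.tn,
            "fn": r.fn,
            "sns": r.sns,
            "spc": r.spc,
            "j": r.youden_j,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if df["sns"].isna().all() and df["spc"].isna().all():
        raise ValueError("all sensitivities and specificities are undefined")

    def iqr(x):
        x = x.dropna()
        return (float(x.quantile(0.25)), float(x.quantile(0.75)))

    return EvaluationSummary(
        per_setting=df,
        median_sns=float(df["sns"].median()),
        median_spc=float(df["spc"].median()),
        median_j=float(df["j"].median()),
        iqr_sns=iqr(df["sns"]),
        iqr_spc=iqr(df["spc"]),
    )


# ---------------------------------------------------------------------------
# bivariate random-effects summary ROC


@dataclass
class SrocSummary:
    bivariate_mean: np.ndarray  # (logit sns, logit spc)
    covariance: np.ndarray  # 2 x 2 between-setting covariance
    slope: float  # d logit(TPR) / d logit(FPR), >= 0
    auc: float
    n_settings: int
    converged: bool = True

    def tpr(self, fpr):
        """Summary ROC curve: TPR as a function of FPR in (0, 1).

        The curve follows the hierarchical-SROC correspondence: on the
        (logit TPR, logit FPR) plane it passes through the pooled summary
        point with slope equal to the ratio of between-setting standard
        deviations, which is nonnegative by construction — the shape a
        summary ROC must have even when the between-setting correlation of
        sensitivity and specificity is positive.
        """
        fpr = np.asarray(fpr, dtype=float)
        x = logit(np.clip(fpr, 1e-12, 1 - 1e-12))  # logit FPR
        mu_sens, mu_spec = self.bivariate_mean
        mu_fpr = -mu_spec
        return expit(mu_sens + self.slope * (x - mu_fpr))


def _logit_pairs(settings):
    """(logit sns, logit spc) with within-setting variances.

    ``settings`` is an iterable of ClassificationResult or of tuples
    ``(tp, fn, tn, fp)``.  Degenerate 0/1 proportions get the continuity
    correction (x + 0.5) / (n + 1); settings with an undefined proportion
    (zero denominator) are dropped.
    """
    ys, variances = [], []
    for s in settings:
        if isinstance(s, ClassificationResult):
            tp, fn, tn, fp = s.tp, s.fn, s.tn, s.fp
        else:
            tp, fn, tn, fp = s
        n1, n0 = tp + fn, tn + fp
        if n1 == 0 or n0 == 0:
            continue
        x1, m1 = (tp, n1) if 0 < tp < n1 else (tp + 0.5, n1 + 1.0)
        x0, m0 = (tn, n0) if 0 < tn < n0 else (tn + 0.5, n0 + 1.0)
        ys.append([logit(x1 / m1), logit(x0 / m0)])
        variances.append([1.0 / x1 + 1.0 / (m1 - x1), 1.0 / x0 + 1.0 / (m0 - x0)])
    return np.asarray(ys), np.asarray(variances)


def _nll(params, y, v):
    mu = params[:2]
    l11, l21, l22 = np.exp(params[2]), params[3], np.exp(params[4])
    psi = np.array([[l11**2, l11 * l21], [l11 * l21, l21**2 + l22**2]])
    total = 0.0
    for i in range(y.shape[0]):
        sigma = psi + np.diag(v[i])
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
        if det <= 0:
            return 1e10
        r = y[i] - mu
        quad = (
            sigma[1, 1] * r[0] ** 2
            - 2 * sigma[0, 1] * r[0] * r[1]
            + sigma[0, 0] * r[1] ** 2
        ) / det
        total += 0.5 * (np.log(det) + quad)
    return total


def sroc_auc(
    settings,
    n_grid: int = 2001,
    _optimizer: str = "lbfgs",
) -> SrocSummary:
    """Fit the bivariate random-effects model and integrate the summary ROC.

    Parameters
    ----------
    settings : iterable
        Per-setting ClassificationResult objects (or (tp, fn, tn, fp)
        tuples) with defined sensitivity and specificity.
    n_grid : int
        Trapezoid nodes for the AUC integral over FPR in [0, 1].
    """
    y, v = _logit_pairs(settings)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 settings with defined sns and spc")

    mu0 = y.mean(axis=0)
    cov0 = np.cov(y.T) if y.shape[0] > 1 else np.eye(2)
    cov0 = cov0 + 1e-6 * np.eye(2)
    l11 = np.sqrt(max(cov0[0, 0], 1e-6))
    l21 = cov0[0, 1] / l11
    l22 = np.sqrt(max(cov0[1, 1] - l21**2, 1e-6))
    x0 = np.array([mu0[0], mu0[1], np.log(l11), l21, np.log(l22)])

    if _optimizer == "lbfgs":
        res = optimize.minimize(_nll, x0, args=(y, v), method="L-BFGS-B")
    else:
        res = optimize.minimize(
            _nll,
            x0 + 0.1,
            args=(y, v),
            method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10},
        )
    converged = bool(res.success)
    mu = res.x[:2]
    l11, l21, l22 = np.exp(res.x[2]), res.x[3], np.exp(res.x[4])
    psi = np.array([[l11**2, l11 * l21], [l11 * l21, l21**2 + l22**2]])

    # The sd-ratio slope is identified only when real between-setting
    # heterogeneity exists on both axes.  When a variance component is
    # negligible against the within-setting sampling noise (settings pinned
    # at an operating corner), the ratio is an arbitrary 0/0 and the curve
    # defaults to the symmetric ROC through the pooled summary point — the
    # zero-heterogeneity limit.
    floor = 0.1 * np.median(v, axis=0)
    if psi[0, 0] < floor[0] or psi[1, 1] < floor[1]:
        slope = 1.0
    else:
        slope = float(np.sqrt(psi[0, 0] / psi[1, 1]))

    summary = SrocSummary(
        bivariate_mean=mu,
        covariance=psi,
        slope=float(slope),
        auc=0.0,
        n_settings=y.shape[0],
        converged=converged,
    )
    fpr = np.linspace(0.0, 1.0, n_grid)
    # endpoints: the logit curve has well-defined limits 0/1 or expit(const)
    tpr = summary.tpr(np.clip(fpr, 1e-9, 1 - 1e-9))
    summary.auc = float(np.trapezoid(tpr, fpr))
    return summary
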