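"""Block-structured individual-level simulation and its summary statistics.

The generative model mirrors the setting that makes multivariable MR
fragile: exposures come in blocks that share genetics.

* Genotypes: n x p biallelic dosages, ``G_j ~ Binomial(2, maf_j)`` with
  per-SNP minor-allele frequencies drawn uniformly from ``maf``.
* SNPs and exposures are partitioned into B equal blocks; the SNPs of
  block b affect only the exposures of block b, with effects drawn as
  ``|N(gamma_effect, (gamma_cv * gamma_effect)^2)|``.  Small ``gamma_cv``
  makes within-block SNP-exposure columns nearly parallel — strong
  marginal instruments that are conditionally weak.
* A single shared standard-normal confounder U adds
  ``confounder_effect_x`` to every exposure and ``confounder_effect_y``
  to the outcome, creating the (weaker) between-block correlation.
* Outcome: ``Y = X beta + confounder_effect_y * U + noise``, continuous;
  ``beta`` is sparse (default: every exposure of the first
  ``max(1, round(B/4))`` blocks is causal).

Summary statistics are produced the way GWAS produce them: a separate
per-SNP simple linear regression (with intercept) of each exposure and of
the outcome on each genotype column, yielding estimates and standard
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import OutcomeStats, SnpExposureMatrix
from .mr import instrument_strength

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_causal_beta",
    "simulate_dataset",
    "calibrate_sample_size",
    "one_sample_equivalence_check",
    "principal_angle_distance",
]


def default_causal_beta(K: int, B: int, effect: float = 0.1) -> np.ndarray:
    """Sparse causal vector: all exposures of the first max(1, B//4 rounded)
    blocks carry ``effect``; the rest are null."""
    n_causal_blocks = max(1, int(round(B / 4)))
    beta = np.zeros(K)
    size = K // B
    beta[: n_causal_blocks * size] = effect
    return beta


@dataclass
class SimulationConfig:
    """Parameters of the block-structured data-generating mechanism."""

    n: int = 10_000
    p: int = 12
    K: int = 6
    B: int = 2
    maf: tuple[float, float] = (0.1, 0.5)
    gamma_effect: float = 0.3
    gamma_cv: float = 0.25  # relative sd of within-block effect heterogeneity
    confounder_effect_x: float = 0.5
    confounder_effect_y: float = 0.5
    beta: np.ndarray | None = None  # K-vector; None -> default_causal_beta
    beta_effect: float = 0.1
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.K % self.B or self.p % self.B:
            raise ValueError("K and p must be divisible by the block count B")
        lo, hi = self.maf
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf range must lie in (0, 0.5]")
        if self.n <= self.p:
            raise ValueError("need n > p")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (self.K,):
                raise ValueError("beta must have length K")

    def resolved_beta(self) -> np.ndarray:
        if self.beta is not None:
            return self.beta
        return default_causal_beta(self.K, self.B, self.beta_effect)


@dataclass
class SimulatedDataset:
    """Individual-level draws plus the derived two-sample summary statistics."""

    config: SimulationConfig
    genotypes: np.ndarray  # n x p dosages
    exposures_individual: np.ndarray  # n x K
    outcome_individual: np.ndarray  # n
    gamma_true: np.ndarray  # p x K
    truth: np.ndarray  # K bools, causal flags
    summary: SnpExposureMatrix
    outcome_summary: OutcomeStats

    def normalized_genotypes(self) -> np.ndarray:
        """Column-centered, unit-norm genotype view (so gamma-hat is on the
        standardized-effect scale used by the one-sample equivalence)."""
        Gc = self.genotypes - self.genotypes.mean(axis=0)
        norms = np.linalg.norm(Gc, axis=0)
        return Gc / norms


def _marginal_regressions(G: np.ndarray, T: np.ndarray):
    """Per-SNP simple OLS (with intercept) of each trait column on each
    genotype column, vectorized.  Returns (estimates, ses), shape p x K."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    Tc = T - T.mean(axis=0)
    sxx = np.sum(Gc**2, axis=0)  # p
    if np.any(sxx == 0):
        raise ValueError("monomorphic genotype column; widen the maf range")
    sxy = Gc.T @ Tc  # p x K
    syy = np.sum(Tc**2, axis=0)  # K
    slope = sxy / sxx[:, None]
    sse = np.maximum(syy[None, :] - sxy**2 / sxx[:, None], 0.0)
    se = np.sqrt(sse / ((n - 2) * sxx[:, None]))
    return slope, se


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the block-structured mechanism."""
    rng = np.random.default_rng(config.rng_seed)
    n, p, K, B = config.n, config.p, config.K, config.B
    snps_per_block = p // B
    exp_per_block = K // B

    maf = rng.uniform(config.maf[0], config.maf[1], size=p)
    # Binomial(2, maf) dosage as the sum of two Bernoulli draws; much faster
    # than elementwise binomial sampling at GWAS-scale n
    G = (
        (rng.random((n, p)) < maf).astype(float)
        + (rng.random((n, p)) < maf)
    )

    gamma_true = np.zeros((p, K))
    for b in range(B):
        rows = slice(b * snps_per_block, (b + 1) * snps_per_block)
        cols = slice(b * exp_per_block, (b + 1) * exp_per_block)
        eff = rng.normal(
            config.gamma_effect,
            config.gamma_cv * config.gamma_effect,
            size=(snps_per_block, exp_per_block),
        )
        gamma_true[rows, cols] = np.abs(eff)  # sign fixed positive

    U = rng.standard_normal(n)
    X = (
        G @ gamma_true
        + config.confounder_effect_x * U[:, None]
        + config.noise_sd_x * rng.standard_normal((n, K))
    )
    beta = config.resolved_beta()
    Y = (
        X @ beta
        + config.confounder_effect_y * U
        + config.noise_sd_y * rng.standard_normal(n)
    )

    gamma_hat, gamma_se = _marginal_regressions(G, X)
    Gamma_hat, Gamma_se = _marginal_regressions(G, Y[:, None])

    snp_ids = [f"rs{j + 1}" for j in range(p)]
    exposure_ids = [f"X{k + 1}" for k in range(K)]
    summary = SnpExposureMatrix(snp_ids, exposure_ids, gamma_hat, gamma_se)
    outcome = OutcomeStats(snp_ids, Gamma_hat.ravel(), Gamma_se.ravel())
    return SimulatedDataset(
        config=config,
        genotypes=G,
        exposures_individual=X,
        outcome_individual=Y,
        gamma_true=gamma_true,
        truth=beta != 0,
        summary=summary,
        outcome_summary=outcome,
    )


def expected_dosage_variance(maf: tuple[float, float]) -> float:
    """E[2 m (1 - m)] for m ~ Uniform(maf)."""
    a, b = maf
    e1 = (a + b) / 2.0
    e2 = (a * a + a * b + b * b) / 3.0
    return 2.0 * (e1 - e2)


def sample_size_for_mean_f(config: SimulationConfig, target: float) -> int:
    """Analytic n for a target mean F-statistic under this mechanism.

    For a SNP in an exposure's own block, E[F_j] ~ 1 + n g2 v / s2 with
    g2 = E[gamma_jk^2], v = E[Var(G_j)] and s2 the residual exposure
    variance of the marginal regression; SNPs of other blocks contribute
    F ~ 1.  Averaging over all p SNPs dilutes the excess by the block
    count B:  mean F ~ 1 + n g2 v / (B s2).
    """
    v = expected_dosage_variance(config.maf)
    g2 = config.gamma_effect**2 * (1.0 + config.gamma_cv**2)
    per_snp = g2 * v
    var_x = (
        (config.p // config.B) * per_snp
        + config.confounder_effect_x**2
        + config.noise_sd_x**2
    )
    resid = var_x - per_snp
    n = (target - 1.0) * config.B * resid / per_snp
    return max(int(round(n)), config.p + 2)


def _target_statistic(config: SimulationConfig, target: str, n_reps: int) -> float:
    vals = []
    for r in range(n_reps):
        ds = simulate_dataset(replace(config, rng_seed=config.rng_seed + 1000 + r))
        strength = instrument_strength(ds.summary)
        if target == "mean_f":
            vals.append(float(np.mean(strength.mean_f)))
        elif target == "mean_cfs":
            vals.append(float(np.mean(strength.conditional_f)))
        else:
            raise ValueError("target must be 'mean_f' or 'mean_cfs'")
    return float(np.mean(vals))


def calibrate_sample_size(
    config: SimulationConfig,
    target: str,
    value: float,
    n_bracket: tuple[int, int] = (500, 400_000),
    rel_tol: float = 0.10,
    n_reps: int = 3,
    max_iter: int = 25,
) -> SimulationConfig:
    """Bisection on n so a Monte-Carlo estimate of mean F (or mean CFS)
    hits ``value`` within ``rel_tol`` relative tolerance.

    Uses a fixed seed schedule derived from ``config.rng_seed`` so the
    search is deterministic.  Both statistics are monotone increasing in n
    for this mechanism, which makes bisection valid.
    """
    lo, hi = n_bracket
    lo = max(lo, config.p + 1)
    f_lo = _target_statistic(replace(config, n=lo), target, n_reps)
    if value <= f_lo:
        if abs(f_lo - value) > rel_tol * max(abs(value), 1e-12):
            warnings.warn(
                f"target {target}={value} is at or below the value {f_lo:.3g} "
                f"achieved at the minimal n={lo}; returning minimal n"
            )
        return replace(config, n=lo)
    f_hi = _target_statistic(replace(config, n=hi), target, n_reps)
    if value > f_hi:
        raise ValueError(
            f"bracket exhausted: {target} reaches only [{f_lo:.3g}, {f_hi:.3g}] "
            f"for n in {n_bracket}, target {value}"
        )
    for _ in range(max_iter):
        mid = int(round(np.sqrt(lo * hi)))  # bisect in log n
        f_mid = _target_statistic(replace(config, n=mid), target, n_reps)
        if abs(f_mid - value) <= rel_tol * abs(value):
            return replace(config, n=mid)
        if f_mid < value:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1:
            break
    return replace(config, n=int(round(np.sqrt(lo * hi))))


def principal_angle_distance(A: np.ndarray, B: np.ndarray) -> float:
    """sin of the largest principal angle between the column spans of A, B."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    s = np.clip(s, -1.0, 1.0)
    return float(np.sqrt(max(0.0, 1.0 - s.min() ** 2)))


def one_sample_equivalence_check(
    dataset: SimulatedDataset, m: int, orthonormalize: bool = False
) -> dict:
    """Compare PCA loadings of the fitted one-sample predictor with PCA of
    the summary-statistic matrix.

    With normalized genotypes G (columns centered, unit norm) the fitted
    exposure matrix is ``Xhat = G gamma_hat`` and ``Xhat' Xhat`` approaches
    ``gamma_hat' gamma_hat`` as G's columns decorrelate, so the two loadings
    subspaces coincide asymptotically.  ``orthonormalize=True`` replaces G
    by an exactly orthonormal basis, making the identity exact at any n.
    """
    gamma_hat = dataset.summary.gamma
    Gn = dataset.normalized_genotypes()
    if orthonormalize:
        Gn, _ = np.linalg.qr(Gn)
    Xhat = Gn @ gamma_hat
    _, _, Vt_x = np.linalg.svd(Xhat, full_matrices=False)
    _, _, Vt_g = np.linalg.svd(gamma_hat, full_matrices=False)
    dist = principal_angle_distance(Vt_x[:m].T, Vt_g[:m].T)
    return {"m": m, "distance": dist, "n": dataset.config.n}
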