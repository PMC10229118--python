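# Methods

## Model and estimation

Two-sample summary-data MR treats the per-SNP association estimates as
data.  The IVW MVMR estimate minimises

    Q_A(β) = Σ_j (Γ̂_j − Σ_k β_k γ̂_jk)² / σ²_Aj ,

with the working model σ²_Aj = σ²_Yj (the no-measurement-error, NOME,
assumption): weighted least squares of Γ̂ on the columns of γ̂ through the
origin, weights 1/σ²_Yj.  No intercept is fitted anywhere (summary
associations are centred at zero under no effect).  Inference is Wald-type
with normal quantiles, the summary-data convention; with a small number of
instruments the normal approximation is the binding assumption either way.
The full variance model — adding Σ_k β²_k σ²_kj and, when the caller
supplies per-SNP K×K covariance matrices, the cross-exposure terms
2 β_l β_k σ_lkj — is available for evaluating Q_A at the fitted β.  The
covariance terms default to zero: estimating them (e.g. from LD-score
regression intercepts) is outside this package's scope, and a hook accepts
user-supplied matrices.

Instrument strength per exposure: the mean F-statistic
F_k = (1/p) Σ_j (γ̂_jk/σ_jk)², and the conditional F-statistic
CFS_k = Q_Xk / (p − (K−1)), where Q_Xk is the weighted heterogeneity of
the residual of regressing column k on the other columns by origin-through
OLS.  The printed variance expression for that residual is self-referential
in the source material; it is implemented as the measurement-error variance
of the residual, σ²_kj + Σ_m δ̂²_m σ²_mj (plus covariance terms when
supplied).  Rank deficiency of the exposure matrix is detected at a
relative singular-value threshold of 1e-10 and is a hard error naming the
collinear columns: silently "solving" the multicollinear design is the
failure mode this workflow exists to avoid.

## Decompositions

All three reductions operate on the *uncentered* γ̂ (rows = SNPs).  Scores
are always `γ̂ @ loadings` — the uncentered cross-product is what makes the
two-sample analysis approximately a one-sample PCA (X̂ᵀX̂ = γ̂ᵀγ̂ for
normalised genotypes), and the second-step MR consumes the scores in place
of γ̂.  Loadings columns are unit-norm; component signs are fixed by making
each column's largest-magnitude entry positive (sign is not identified).

* **PCA** — plain SVD.  Dense loadings: every exposure contributes to
  every component.
* **Elastic-net sparse PCA** — the regression reformulation with Gram
  matrix G = γ̂ᵀγ̂: alternately (i) solve per-component elastic nets
  ξ_j = argmin (a_j−ξ)ᵀG(a_j−ξ) + λ₂‖ξ‖² + λ₁‖ξ‖₁ (coordinate descent),
  and (ii) update the orthonormal basis A from the SVD of GΞ.  A
  per-component cardinality cap is supported in place of λ₁: the ridge
  solution is soft-thresholded at its (c+1)-th largest magnitude, leaving
  at most c nonzero loadings (ties broken by column order, for
  determinism).  Non-convergence at max_iter raises a warning, not an
  error; a component shrunk entirely to zero is kept as a zero column with
  a warning.
* **SCA (rotation toward sparsity)** — the m leading principal loadings
  are rotated by an orthogonal matrix fitted by alternating
  soft-thresholding (sparse target) and orthogonal-Procrustes steps,
  starting from a varimax rotation, which already concentrates loading
  mass and makes the fixed point block-aligned.  Because the rotation is
  orthogonal the m-dimensional subspace and its total explained variance
  are exactly PCA's.  Reported loadings are the thresholded, renormalised
  columns (exact zeros where thresholded).  The default threshold is the
  largest value on a small quantile grid such that the surviving entries
  retain ≥ 95 % of every rotated column's squared norm; the variance
  accounting judges surviving entries unshrunk, since only the zero
  pattern matters for it.

## Component retention

Eigenvalues for retention are computed from γ̂ with columns scaled to unit
norm but **not centred** (cross-product trace K).  Rationale: the
components that enter MR are directions of the uncentered cross-product;
with B mutually exclusive blocks of positive associations, centring turns
the B block patterns into B−1 anti-correlated contrasts and the criterion
would systematically miss one real component.  On the uncentered trace-K
scale a non-informative column still contributes eigenvalue mass ≈ 1, so
the conventional cutoffs keep their reference level.

* **KSS cutoff**: retain components with eigenvalue above
  1 + 2·√((K−1)/(p−1)).
* **Permutation test**: each null draw shuffles every column independently
  *and randomises entry signs*; the observed eigenvalue at rank k must
  exceed the 0.95 null quantile at that rank, and the retained count is
  the leading consecutive run.  Two deliberate departures from the naive
  recipe, both forced by its measured behaviour: (a) without sign
  randomisation the shared positive column means survive shuffling and
  inflate the null lead eigenvalue, making the test blind to the first
  real component (on two-block data it retains 1, never 2); under the
  no-association null the estimate signs are arbitrary, so sign
  randomisation is a valid augmentation.  (b) With a mean comparison the
  observed spectrum of pure noise is itself a draw from the permutation
  distribution, so each rank is a ~50 % coin flip and the test retains ~K/2
  spurious components; a high null quantile restores type-I behaviour
  (0 retained on pure noise in ≥ 90 % of runs).  The mean comparison and a
  no-flip scheme remain available as options.

In the pipeline, the retained count m\* is decided on the PCA spectrum for
every reduction method (sparse rotations live in the same leading
subspace), and the sparse method is then fitted with m\* components.  The
sparse-PCA cardinality defaults to ceil(K/m\*) — with ~97 exposures and 6
components this gives ≈ 16 nonzero loadings per component, the sparsity
level used in applications of this workflow.

Instrument strength of a component with loadings v is the delta-method
F-statistic F = (1/p) Σ_j (γ̂_j·v)² / (vᵀ diag(σ²_1j..σ²_Kj) v), i.e. the
single-exposure mean F applied to the transformed exposure; it reduces to
F_k for a coordinate vector and is invariant to rescaling v.  This is the
natural propagation consistent with treating the MVMR fit on
(near-)orthogonal scores as per-component univariable analyses.

## Pipeline

Reduce → retain → assess strength → IVW MVMR of the untransformed Γ̂ on
the retained scores, component tests at α/B with B the retained count.
Zero retained components yields a structured empty result with a warning.
Outcome standard errors enter the weights unmodified; first-stage
uncertainty is reported through the component F-statistics rather than
propagated into the weights.  The pipeline is bit-reproducible given the
seed and configuration.

## Synthetic data

The generator emulates the structure that makes joint MVMR conditionally
weak: p SNPs and K exposures in B equal blocks; genotypes
G_j ~ Binomial(2, maf_j), maf ~ U(0.1, 0.5) (avoids rare-variant
instability at simulation scale); block-b SNPs affect only block-b
exposures with effects |N(g, (cv·g)²)| (sign fixed positive); one shared
standard-normal confounder U feeding every exposure and the outcome —
the minimal mechanism for between-block correlation; continuous outcome
Y = Xβ + c_y·U + ε.  Summary statistics come from per-SNP simple OLS with
intercept, exactly as GWAS produce them.  Not emulated: linkage
disequilibrium (instruments are independent, matching the pruned-instrument
setting), binary outcomes, pleiotropy via unmodelled exposures, allele
frequency/harmonisation issues.  Passing tests therefore demonstrate the
statistical machinery under the stated mechanism, not robustness to those
real-data complications.

Sample sizes are set analytically: mean F ≈ 1 + n·g²(1+cv²)·v̄/(B·σ²_resid)
(the B in the denominator because only 1/B of SNPs instrument a given
exposure), inverted for n; a Monte-Carlo bisection (`calibrate_sample_size`)
is available when the analytic route does not apply.

### Study conditions

* **Illustrative (two blocks of three)**: g = 0.5, cv = 0.25, confounder
  0.5/0.5, exposure noise sd 0.5, outcome noise sd 1, β = 0.3 on block 1;
  n-grid (600, 2500, 8000, 25000) spanning mean CFS ≈ 2–70; two components
  fixed a priori; all tests at α/2.  β was chosen by a design analysis so
  that joint-MVMR power actually transitions across the grid (Wald z from
  ~1 to ~6): a grid where every method is saturated or hopeless would not
  discriminate.
* **High-dimensional grid**: (K, B) ∈ {(32,4), (30,6), (60,4), (60,6)}
  (the 30–60 exposure / 4–6 block span realised as divisible
  combinations), p = B·round(1.5K/B) ≈ 1.5 SNPs per exposure (the
  instrument-to-exposure ratio of the workflow's real application),
  cv = 0.12 — calibrated so the setting-mean conditional F spans ≈ 1–12
  across the F-grid, the conditionally-weak regime of interest — three
  sample sizes per design targeting mean F ∈ {220, 500, 1100}, 50
  replicates per setting, β = 0.45 on the causal blocks (first
  max(1, round(B/4)) blocks causal; whole blocks, so that sparse
  components map cleanly onto causal sets).  MVMR's Wald statistic
  saturates in β (the outcome variance grows with β), so larger causal
  effects sharpen the contrast between component-level and per-exposure
  power without giving MVMR free power.

## Evaluation

An exposure is a *major contributor* to a component iff its |loading|
exceeds the component's mean |loading| over all K entries (zeros included
— the rule must stay sparsity-sensitive; absolute values because loadings
are sign-indefinite).  An exposure is called positive iff it is a major
contributor to any component significant at the corrected level; a
TP-producing call takes precedence over an FP-producing one per exposure
(each exposure gets exactly one call).  For per-exposure MVMR the call is
the exposure's own Wald test.  Per setting, counts are pooled over
replicates; SNS = TP/(TP+FN), SPC = TN/(TN+FP), J = SNS + SPC − 1, with
zero-denominator ratios recorded as missing, never as zero.  Aggregates
across settings are medians and interquartile ranges; J is aggregated as
the median of per-setting J (not J of the medians).  A run that retains
zero components contributes an all-negative classification, not a dropped
run.

The summary ROC pools per-setting (sens, spec) pairs by a bivariate
random-effects model on the logit scale: within-setting
binomial-approximation variances (1/x + 1/(n−x)), degenerate proportions
continuity-corrected as (x+0.5)/(n+1), between-setting covariance
unstructured, fitted by maximum likelihood (L-BFGS on a log-Cholesky
parameterisation).  The summary curve follows the hierarchical-SROC
correspondence: on the (logit TPR, logit FPR) plane it passes through the
pooled summary point with slope equal to the ratio of between-setting
standard deviations (nonnegative by construction).  When either variance
component is negligible against the within-setting sampling noise (the
settings pinned at an operating corner), that ratio is an unidentified
0/0 and the curve defaults to the symmetric ROC (slope 1) through the
summary point — the zero-heterogeneity limit.  AUC is a 2001-node
trapezoid over the full FPR ∈ [0, 1] range (an extrapolated summary).

**Caveat**: the summary-ROC AUC is an extrapolation from the observed
operating points.  When a method's per-setting points are pinned at a
corner (sensitivity exactly 1, or FPR exactly 0), the AUC is governed by
the continuity corrections and the slope policy rather than by
discrimination, and is best read alongside the median
sensitivity/specificity, which are artifact-free.

## Numerical choices and degenerate inputs

* Collinearity threshold 1e-10 (relative); weighted design matrices are
  formed with √w scaling before factorisation.
* Sparse-PCA coordinate descent: 100 sweeps max per component, tolerance
  1e-10; outer loop tolerance 1e-6 on the loadings change, 200 iterations.
* All-zero loading columns are dropped from the retained set before the
  second-step fit; a fully empty retained set returns an empty fit with a
  warning.
* File I/O writes 17 significant digits and reads with round-trip float
  parsing, so write∘read is bitwise on doubles.
* Missing values are rejected, not imputed; duplicate SNP or exposure ids
  are hard errors.

## Known limitations

* No allele/strand harmonisation — inputs must already be harmonised.
* Cross-exposure within-SNP covariances default to zero; supplying them is
  the caller's responsibility.
* The permutation test refits the decomposition per permutation; for very
  large K the pipeline's PCA-spectrum shortcut is the intended path.
* Sparse components are only approximately orthogonal; the second-step
  joint fit accounts for their sample correlation through the joint WLS,
  and no further adjustment is made.
* The SROC corner-cluster caveat above.
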