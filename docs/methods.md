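# Methods

This note records the statistical models the package implements, the
numerical choices behind them, and what the synthetic-data experiments
do and do not demonstrate.

## Stage 1: pooling correlation matrices

**Fixed effects.**  Studies are assumed to share one population
correlation matrix P.  Study i's observed correlation matrix S_i
(over its observed variable subset) is modeled as Σ_i = D_i P D_i with a
free positive diagonal D_i per study — nuisance scalings that make the
correlation-matrix input well-posed as a covariance-structure problem.
The discrepancy

    F = Σ_i (N_i − 1) [ ln|Σ_i| + tr(S_i Σ_i⁻¹) − ln|S_i| − p_i ]

is minimized over (vech P, all D_i); its minimum is the homogeneity χ²
with df = Σ_i p_i(p_i−1)/2 − p(p−1)/2.  The (N_i − 1) multiplier follows
the sample-covariance convention.  The asymptotic covariance of
vech(P̂) is the corresponding block of the inverse observed information,
with the information computed as half the Hessian of F by central finite
differences of the analytic gradient (the gradient itself is exact).

Studies with missing correlations contribute a reduced block: variables
are deleted greedily (most missing pairs first) until the submatrix is
complete.  No imputation is performed.

**Random effects.**  The observed correlation vector r_i is modeled as
Normal(μ, V_i + T²) on its observed subvector, where V_i is the known
large-sample (Olkin–Siotani) sampling covariance and T² the between-study
covariance.  Estimation is full-information ML over all studies.  T² may
be diagonal (default; the usual restriction when k is modest) or full
(Cholesky-parameterized).  The covariance of μ̂ is the inverse expected
information Σ_i (V_i + T²)⁻¹ — exact for the mean block of a normal
model, which is block-orthogonal to the variance parameters.

V_i is evaluated by default at the n-weighted pooled correlation matrix
(two-pass), so V_i = V_base / n_i; this stabilizes the weights of small
studies.  A `eval_point="study"` flag switches to study-specific
evaluation for sensitivity analysis.

Per-correlation heterogeneity is summarized as I² = τ² / (τ² + ṽ), with
ṽ the harmonic mean of the per-study sampling variances — a standard
"typical variance" choice that is insensitive to a single large study.

## Stage 2: weighted least squares on the pooled correlations

Models are parsed from a small lavaan-like syntax into RAM form
(asymmetric paths A, symmetric covariances S); one implied-matrix engine
serves factor, path and hybrid models.  The fit function is
F(θ) = (r − ρ(θ))ᵀ W (r − ρ(θ)) with W the inverse Stage-1 asymptotic
covariance; since that covariance reflects the total sample size, the
minimum of F is the model χ² directly.  Standard errors are
sqrt(diag((ΔᵀWΔ)⁻¹)) with Δ the central-difference Jacobian of ρ at the
optimum (step 1e−6); confidence intervals are Wald.  (The original
software for this methodology reports likelihood-based CIs; that choice
affects interval widths, not estimates, and Wald intervals are used here
throughout.)

**Standardized metric and remainders.**  Latent variances are fixed at
1; exogenous observed variables get fixed unit variance with free
covariances (correlations) where declared.  Residual variances of
endogenous observed variables are never free parameters: they are solved
per evaluation so that every implied diagonal element equals exactly 1
(for a factor row, 1 minus the communality; for a mediator v3 in the
path example, ψ33 = 1 − (β31² + β32² + 2β31β32ψ12)).  Mediation makes
the system triangular rather than diagonal and it is solved as a linear
system in general.  A negative remainder (implied communality above 1)
is an inadmissible point: the top-level `implied_matrix` raises, the
optimizer works with the check disabled, and a final solution with a
negative remainder is reported as non-converged.

**Multiple groups.**  The joint fit stacks per-group weighted residuals,
each subgroup keeping its own Stage-1 weight matrix; parameters sharing
a cross-group-equated label are forced identical.  With no constraints
the joint χ² and df are exactly the sums of per-group values, which the
tests assert as a bookkeeping identity.  Each equated label adds (G − 1)
to the df.  Δχ² between nested constraint sets is referred to
χ²(Δdf); a negative Δχ² beyond 1e−6 is treated as an optimization
failure, not a test result.

Factor-loading sign indeterminacy is resolved at reporting time by
flipping any factor whose first declared loading is negative — a
convention only, with no effect on fit.

## Optimization and convergence

All Stage-1 iterates stay in the valid region through unconstrained
reparameterizations: correlations via atanh, scalings and between-study
variances via logs, full T² via a Cholesky factor with log diagonal.
L-BFGS-B with analytic gradients does the work; the per-study
computations are batched across studies when all studies observe all
variables, which is what makes the Monte-Carlo experiments cheap.

The objective is scaled before optimization — fixed effects by
1/Σ(N_i − 1), random effects by 1/k — so that gradient magnitudes are
O(1) regardless of total sample size.  "Converged" means: the optimizer
reached a point whose (projected) gradient max-norm is below 1e−6
(fixed) or 1e−4 (random, relative to the objective magnitude), the
information matrix is positive definite, and — for Stage 2 — all
remainder residuals are nonnegative.  A between-study log-variance below
−15 is reported as the τ² = 0 boundary.  Up to three jittered restarts
are attempted on failure; Stage 2 additionally restarts its
Levenberg–Marquardt solver around an unweighted least-squares start.

This operationalization is deliberate: the methodology literature
reports substantial non-convergence rates for random-effects MASEM in
other software, but "converged" is software-specific.  With these
(fairly forgiving, analytically-gradient-driven) criteria the package
converges in essentially all replications of the default experiment, so
the simulation reports convergence *orderings* (subgroup ≤ overall,
nondecreasing in k), not absolute percentages.

## The synthetic-data generator

`masem.simulate` emulates a two-subgroup meta-analytic universe built on
the four-variable mediation model (v3 ~ v1 + v2, v4 ~ v3, v1 ~~ v2):

* subgroup mean correlation vectors are derived from the path
  coefficients through the model's implied matrix — defaults
  β31 = .265, β32 = −.307, ψ12 = −.329, and β43 = .288 (subgroup 1)
  vs .388 (subgroup 2), a .10 difference in one path;
* each study's population vector adds independent normal between-study
  deviations with SD 0.10 per correlation (redrawn until the assembled
  matrix is positive definite).  The 0.10 default is a package choice:
  it produces I² values in the .6–.85 range at n = 200, matching the
  heterogeneity magnitudes typical of the motivating application area;
* each study contributes the sample Pearson correlations of n = 200
  multivariate-normal observations.

Per replication the correct model is fitted to all studies combined and
to each subgroup separately, both with diagonal T².  Metrics follow
standard Monte-Carlo conventions: relative bias 100(mean θ̂ − θ)/θ,
SE bias 100(mean SE − SD(θ̂))/SD(θ̂), computed only over replications in
which all compared analyses converged; convergence proportions use all
replications.  The default is 200 replications per condition (the
package's desk-scale choice; the qualitative conclusions — overall bias
beyond ±5% against both subgroup truths, subgroup bias within ±5% and
SE bias within ±10% at k = 88 — are stable at this scale, with wider
Monte-Carlo error than a 2000-replication run).

**What passing tests do not show.**  The generator draws exactly normal
data, exactly normal between-study deviations, equal n across studies,
complete correlation matrices, and a correctly specified structural
model.  Real meta-analytic data involve ordinal items (Pearson
correlations then underestimate), missing variables by design,
non-normal study populations, and structural misspecification; the
simulation results say nothing about robustness to any of these.
Likewise the homogeneity-χ² and type-I-error calibrations hold under the
null with normal data at n = 200 and do not certify behavior under
severe heterogeneity or tiny per-study n.

## Other numerical choices

* RMSEA = sqrt(max(0, (χ² − df)/(df(n − 1)))) with n the total sample
  size over all groups and no multiple-group multiplier; its 95% CI
  inverts the noncentral-χ² CDF by root-finding on the noncentrality.
* CFI uses the zero-correlation model under the same weight matrix as
  baseline (the baseline is not standardized across software; this one
  is explicit and reproducible).
* SRMR is the RMS of unique off-diagonal residuals; multigroup SRMR is
  the unweighted mean of per-group values.
* Dichotomizing a continuous study-level moderator requires an explicit
  threshold (value > threshold → first group); no split search is
  offered, and per-parameter follow-up testing is expected to use a
  Bonferroni-corrected α.
* The long (tidy) input format with absent rows for missing correlations
  was chosen over stacked square matrices: it is diff-friendly and makes
  missingness explicit.  Variable ordering always comes from the declared
  list, never from file order.

## Known limitations

* Fixed-effects pooling with many variables and studies (e.g. 14
  variables × 28 studies) estimates hundreds of nuisance scalings; the
  observed-information acov at that scale is expensive and the package
  computes it only on request.
* No Fisher-z pooling, no analysis of covariance matrices (and hence no
  unstandardized/weak factorial invariance testing), no polychoric
  corrections for ordinal items, no continuous-moderator meta-regression.
* Likelihood-based CIs and parameter-based (rather than two-stage) MASEM
  are out of scope.
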