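# Methods

## Setting and model

Clusters (providers) `i = 1..I` each contribute a public summary record:
observed outcome total `O_i`, expected total `E_i` under a national
case-mix model, effective size `ñ_i = Σ_j b''(θ⁰_ij)` (for Poisson
outcomes `ñ_i = E_i`; for Normal outcomes `ñ_i = n_i`), optionally the
third-cumulant sum `Σ_j b'''(θ⁰_ij)`, and cluster covariates `W_i`
(assumed mean zero; ingestion centers them and records the offsets).
Patient outcomes follow a canonical-link exponential-family GLM whose
linear predictor contains the quality effect `γ*_i`, observed cluster
confounding `W_i'ν`, and unobserved cluster confounding
`α_i ~ N(0, σ²_α)` (only the first two moments of `α_i` are actually
used). The naive score statistic is `Z_i = (O_i − E_i)/sqrt(a(ψ) ñ_i)`.

## Null moments

For a null cluster (`γ*_i = 0`), conditional on `W_i`:

* **Normal** (`a(ψ) = σ²_ε`), exact:
  `E[Z] = sqrt(n/σ²_ε) W'ν`, `Var[Z] = 1 + (σ²_α/σ²_ε) n`.
* **Poisson**, exact, with `x = W'ν + σ²_α/2`:
  `E[Z] = sqrt(ñ)(e^x − 1)`,
  `Var[Z] = e^x [1 + e^x (e^{σ²_α} − 1) ñ]`.
  Quasi-Poisson (`a(ψ) = ψ > 1`) divides the mean by `sqrt(a(ψ))` and the
  variance by `a(ψ)`, consistent with the `sqrt(a(ψ) ñ)` standardization
  of `Z`; at `a(ψ) = 1` this reduces to the exact Poisson case. `a(ψ)` is
  supplied by the user, never estimated: the patient-level model is assumed
  externally fitted, and summary data carry no information to estimate it.
* **General family**, first order:
  `E[Z] ≈ sqrt(ñ/a(ψ)) W'ν`,
  `Var[Z] ≈ 1 + (Σb'''/ñ) W'ν + (σ²_α/a(ψ)) ñ`.
  The variance approximation can go nonpositive for extreme covariates and
  is floored at `1e−6` with a warning; the exact Normal/Poisson paths never
  need the floor.

Both exact sets of formulas are verified in the test suite against
independent Monte-Carlo oracles that simulate cluster sums directly.

## Robust empirical-null estimation

With unknown outliers present, the likelihood treats the null set
explicitly. Null intervals are `[A_i, B_i] = mean₀_i ± c·sd₀_i` with
`c = 2.5` by default, where `mean₀, sd₀` come from the **robust
initializer**: a Huber M-regression (tuning 1.345) of `z` on the design
rows `sqrt(ñ_i/a(ψ)) W_i` through the origin (the first-order mean), and a
median-of-moments start `σ²₀ = median(max(0, (r_i² − 1)/ñ_i))·a(ψ)` from
its residuals; `π₀` starts at 0.95. The likelihood

```
L(ν, σ²_α, π₀) = Π_{i∈S₀} π₀ φ_i(z_i) · Π_{i∉S₀} (1 − π₀ Q_i),
```

with `S₀ = {i : A_i ≤ z_i ≤ B_i}`, `φ_i` the normal density at the
family-specific null moments and `Q_i` the normal mass of `[A_i, B_i]`, is
maximized by L-BFGS-B on transformed parameters (`log σ²_α`,
scaled-logit `π₀ ∈ (1e−4, 1]`; objective tolerance 1e−8, max 500
iterations; `log(1 − π₀Q_i)` clamped at `log(1e−300)`). After the first
optimum the intervals are recomputed at the fitted moments and the model
refit once (toggleable); the two-stage rule keeps the estimator
deterministic. If fewer than `P` clusters fall inside their intervals the
fit aborts with a diagnostic rather than silently widening intervals.
Optimizer non-convergence is reported on the returned fit, not raised.

The non-robust baseline (`fit_normal_mle`) maximizes the plain normal
likelihood over all clusters (`π₀ = 1`, no truncation); for Normal
outcomes with `σ²_α` fixed at zero it coincides with OLS. With `c = ∞`
the robust fit reduces to this baseline (tested).

The sandwich covariance of `ν̂` is
`(X'X)⁻¹ X'ΩX (X'X)⁻¹` with `X` the design rows restricted to `S₀` and
`Ω = diag(Var[Z_i | W_i, null])` at the fitted parameters.

## Inference

Frequentist: `z*_i = (z_i − Ê[Z|null]) / sqrt(Var̂[Z|null])` compared to a
threshold (default 1.96, strict inequality — scores exactly at the
threshold are not flagged).

Pseudo-Bayesian: `ν` gets a `MVN(0, Σ_prior)` prior (default diagonal with
variance 100 per centered covariate — weakly informative; the flat-prior
limit recovers the Frequentist fit) combined with
`ν̂ ~ MVN(ν, Σ_ν̂)`; the posterior is computed as
`Σ_post = Σ_prior − Σ_prior(Σ_prior+Σ_ν̂)⁻¹Σ_prior`, a form that stays
valid when `Σ_ν̂` is singular (e.g. exactly zero in plug-in mode). The
total confounding factor `Λ_i = exp(W_i'ν + α_i)` is approximately
`Lognormal(W_i'm_post, W_i'Σ_post W_i + σ²_α)` — `σ²_α` is plugged in as a
known nuisance parameter throughout inference. The corrected measure-ratio
posterior is the Lognormal mixture of `Gamma(O+2, E·λ+2)` densities,
integrated by Gauss–Hermite quadrature (64 nodes) so results are
bit-for-bit reproducible; quantiles come from Brent root-finding on the
mixture CDF. Credible intervals are equal-tailed (matching the
Gamma-quantile convention of registry reporting; highest-density intervals
are not provided), and a provider is flagged when the interval excludes 1.
With `Σ_post = 0` and `σ²_α = 0` the machinery collapses exactly to the
conventional `Gamma(O+2, E+2)` posterior.

## Synthetic-data generators

`gen_estimation_data` emulates a national Poisson evaluation: `I = 200`
clusters, patient counts `n_i` equally spaced (deterministically) from 50
to 450, `W_i ~ N(0,1)`, `α_i ~ N(0, 0.1)`, `X_ij ~ N(−0.4, 0.5)`,
`μ* = −6`, `β = 1`, `ν = 0.25`, and outlier effects `γ*_i = c + 0.5 W_i`
(default effect size `c = 2`) for a configurable fraction of clusters.
All "N(m, v)" parameters are (mean, **variance**) pairs. Outlier indices
are drawn uniformly at random (seeded): because `n_i` is assigned in
increasing order, taking a deterministic prefix would tie outlier status
to cluster size. Cluster totals are drawn as
`O_i ~ Poisson(E_i · exp(γ*_i + νW_i + α_i))`, the exact law of the
patient-level sum. Inference designs pin a "special" first provider
`(W₁, γ*₁)`; low-quality care corresponds to negative `γ*₁`.

`gen_cre_data` generates the correlated-random-effects design with Normal
outcomes: `X_ij ~ N(m_X, 0.25)`, `m_X ~ N(−0.4, 0.25)`, cluster effects
`γ*_i = ξ X̄_i + τ_i` with `ξ = 0.25` and `τ_i ~ N(0, 0.1)` contaminated
by outliers; the centered cluster means `X̄_i` are exposed as the cluster
covariate. The intercept of the underspecified national model absorbs
`ξ·E[X̄]`, so expected totals are defined against the absorbed norm; since
every Normal-family statistic depends on `(O, E)` only through `O − E`,
the expected totals are normalized to a positive baseline (`E = 4n`)
without changing any estimate.

Experiments (`run_estimation_study`, `run_cre_study`,
`run_inference_study`, `run_coverage_table`) are pure functions of
(config, seed): replicate seeds are spawned from a single seed sequence,
failures are counted and excluded, and probabilities carry binomial
Monte-Carlo standard errors. Inference studies estimate `(ν, σ²_α)` per
replicate by default (the honest pipeline); a plug-true mode exists for
calibration checks.

What the generators do **not** emulate: informative cluster size (size is
independent of quality), spatial correlation in `α_i`, missing covariates,
and reporting-period artifacts of real registry extracts. Passing tests
therefore show correctness of the estimator under its assumed sampling
model, not robustness to those features of real data.

## Count scale and identifiability

At the published generating parameters (`μ* = −6`, `n_i ≤ 450`) the
per-cluster expected counts are below one (`E_i ∈ [0.11, 0.98]`). Two
consequences, both visible in the acceptance runs and documented
deliberately rather than patched:

* `ν` is still estimated well (the mean formula is exact regardless of
  count scale) and the robustness ordering versus the plain MLE holds, but
  `σ²_α` is essentially unidentified — its variance-inflation signal
  `(e^{σ²_α} − 1)·ñ ≈ 0.05` is invisible against `Var[Z] ≈ 1`, and fits
  return `σ̂²_α ≈ 0`.
* The Z-scores are heavily discrete, so normal-approximation error rates
  (e.g. the 5% level of the corrected score test) and credible-interval
  coverage do not attain their nominal values at this scale; they do at
  informative count scales (tens to hundreds of expected events per
  cluster, the regime provider profiling operates in and the regime used
  by the identification-dependent unit tests, e.g. `μ* = −1`).

Relatedly, the truncation at `c = 2.5` induces a mild downward attenuation
of `σ̂²_α` (about 0.08 recovered for a true 0.1 at `μ* = −1`; `c = ∞` is
unbiased but not robust). This is the classic variance cost of estimating
a null distribution from a central region and is left visible.

## Defaults and knobs that matter

| parameter | default | meaning |
|---|---|---|
| `c` | 2.5 | null-interval half-width in null SDs; `∞` disables robustness |
| `refine` | on | one interval-refinement pass at the first optimum |
| `a(ψ)` | 1 | dispersion; `σ²_ε` for Normal outcomes |
| `threshold` | 1.96 | two-sided corrected-Z flag threshold |
| `level` | 0.95 | credible-interval level |
| `prior_var` | 100 | prior variance per covariate coefficient |
| `n_nodes` | 64 | Gauss–Hermite nodes for the ratio posterior |

Degenerate inputs: all-zero covariate columns yield `ν̂ = 0` and a
variance-only empirical-null fit; rank-deficient covariate designs and
null sets smaller than `P` are hard errors; missing covariate values are
rejected (no imputation mechanism exists in the model).
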