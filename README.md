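# rppclc — robust privacy-preserving cluster-level confounding models

`rppclc` evaluates healthcare providers (or any clusters) against a national
norm using only **public summary statistics** — the observed outcome total
`O_i`, the case-mix-expected total `E_i`, an effective size `ñ_i`, and
cluster-level covariates `W_i` — while adjusting for **observed cluster-level
confounding** (e.g. regional donor-organ availability) and correcting for
**overdispersion from unobserved confounding**. It was built for transplant
center profiling from registry-style reports, where patient-level data are
restricted, but applies to any observed/expected evaluation of clustered
outcomes.

## The model

Patient outcomes are assumed to follow a canonical-link GLM with linear
predictor

```
θ*_ij = μ* + γ*_i + X_ij'β + W_i'ν + α_i,        α_i ~ N(0, σ²_α),
```

where `γ*_i` is the quality effect of interest, `W_i` are observed
cluster-level confounders with effects `ν`, and `α_i` is unobserved
cluster-level confounding. Only the naive score statistics

```
Z_i = (O_i − E_i) / sqrt(a(ψ) ñ_i)
```

are needed. Conditional on `W_i`, a null cluster's Z-score has closed-form
mean and variance in `(ν, σ²_α)` — exactly for Normal and Poisson outcomes,
to first order in general — e.g. for Poisson, with `x = W'ν + σ²_α/2`:

```
E[Z | null]   = sqrt(ñ) (e^x − 1)
Var[Z | null] = e^x [1 + e^x (e^{σ²_α} − 1) ñ]
```

Because real data always contain outlying clusters, `(ν, σ²_α, π₀)` are
estimated by maximizing a **truncated-normal empirical-null likelihood**:
per-cluster null intervals `[A_i, B_i]` are set around the robust initial
fit, clusters inside contribute `π₀ φ_i(z_i)` and clusters outside only the
exceedance mass `1 − π₀ Q_i`. Flagging then proceeds two ways:

* **Frequentist** — corrected scores `z* = (z − Ê[Z|null]) / sqrt(Var̂[Z|null])`
  against ±1.96;
* **Pseudo-Bayesian** — a normal posterior for `ν` (sandwich covariance over
  the null set + MVN prior) propagated through the total confounding factor
  `Λ_i = exp(W_i'ν + α_i) ~ Lognormal`, turning the conventional
  `Gamma(O+2, E+2)` posterior of the measure ratio into a Lognormal mixture
  of `Gamma(O+2, E·λ+2)` densities for the corrected ratio `R*_i`; providers
  are flagged when the 95% equal-tailed credible interval excludes 1.

## Worked example

`examples/evaluate_centers.py` simulates a 200-center evaluation with a
confounder effect `ν = 0.25`, 5% truly low-quality centers, writes the
registry-style CSV, and runs the full pipeline:

```
nu_hat = 0.251  (95% CI 0.185 to 0.317; truth 0.25)
sigma2_alpha_hat = 0.0783  (truth 0.1)
pi0_hat = 0.964, null set size = 188/200

Frequentist flags (corrected Z, threshold 1.96):
flag_freq
null    181
low      12
high      7

10 of the 10 true low-quality centers are flagged by the corrected Z-scores
```

`nu_hat` is the recovered confounding effect with its Wald interval;
`sigma2_alpha_hat` the unobserved-confounding variance; the null set is the
group of centers whose Z-scores fell inside their empirical-null intervals.
A `low` flag means fewer events than expected given both case mix and the
center's confounding profile. The other examples show the robustness of the
estimator to contaminated clusters (`robustness_study.py`), between-cluster
effect estimation under a correlated-random-effects design
(`cre_between_effect.py`), and the naive-vs-adjusted posterior for a single
center (`corrected_posterior.py`).

The same workflows are available from the shell:

```bash
rppclc evaluate --input centers.csv --out results.csv --family poisson
rppclc simulate --design coverage --reps 500 --seed 1 --out coverage.csv
```

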