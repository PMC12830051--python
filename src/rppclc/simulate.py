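"""Synthetic-data generators and Monte-Carlo experiment runners.

The Poisson generator emulates a national provider-profiling study: I = 200
clusters with patient counts n_i equally spaced from 50 to 450, a standard
normal cluster covariate W_i with effect nu = 0.25, unobserved cluster
confounding alpha_i ~ N(0, 0.1), a patient risk factor X_ij ~ N(-0.4, 0.5)
(mean, variance) with effect beta = 1 and population norm mu* = -6, and
outlying clusters whose quality effect is gamma*_i = c + 0.5 W_i.  The
summary statistics exposed to the estimators are exactly the public ones:
O_i (observed count), E_i = sum_j exp(mu* + beta X_ij) (expected count,
also the Poisson effective size) and W_i.

The Normal-outcome generator reproduces the correlated-random-effects
design: the cluster effect is gamma*_i = xi * Xbar_i + tau_i, correlated
with the cluster mean Xbar_i of the patient covariate, with tau_i
contaminated by outliers; feeding Xbar_i through the same machinery as an
observed cluster covariate estimates the between-cluster effect xi from
summaries alone.

All generators and experiments are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ProviderSummary, ProviderTable
from .estimation import fit_normal_mle, fit_rppclc
from .families import FamilySpec
from .inference import (
    RStarPosterior,
    corrected_z,
    flag_bayes,
    flag_frequentist,
    lambda_posterior,
    naive_posterior,
    posterior_nu,
)
from .null_moments import null_moments, zscores

__all__ = [
    "SimStudyConfig",
    "SimStudyResult",
    "gen_estimation_data",
    "gen_cre_data",
    "run_estimation_study",
    "run_cre_study",
    "run_inference_study",
    "run_coverage_table",
]


@dataclass(frozen=True)
class SimStudyConfig:
    """Generating-model parameters and experiment settings.

    Distribution parameters are (mean, variance) pairs.  ``special`` pins
    the first cluster's covariate and quality effect ``(W_1, gamma*_1)``
    for inference studies; all remaining clusters are null unless
    ``outlier_prop > 0``.
    """

    I: int = 200
    n_range: tuple[int, int] = (50, 450)
    mu_star: float = -6.0
    beta: float = 1.0
    nu: float = 0.25
    sigma2_alpha: float = 0.1
    x_mean: float = -0.4
    x_var: float = 0.5
    outlier_prop: float = 0.0
    outlier_c: float = 2.0
    family: str = "poisson"
    seed: int = 0
    reps: int = 100
    # flagging rules
    threshold: float = 1.96
    level: float = 0.95
    prior_var: float = 100.0
    interval_c: float = 2.5
    n_nodes: int = 64
    # special provider (inference designs): (W_1, gamma*_1)
    special: tuple[float, float] | None = None
    use_true_params: bool = False
    # correlated-random-effects design (Normal outcomes)
    xi: float = 0.25
    sigma2_tau: float = 0.1
    sigma2_eps: float = 1.0
    m_x_var: float = 0.25
    x_var_cre: float = 0.25

    def __post_init__(self) -> None:
        if self.n_range[0] < 1 or self.n_range[0] > self.n_range[1]:
            raise ValueError("n_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.outlier_prop < 1.0:
            raise ValueError("outlier_prop must be in [0, 1)")


@dataclass
class SimStudyResult:
    """Aggregated Monte-Carlo outputs of one experiment."""

    design: str
    metrics: dict
    mc_se: dict
    reps_completed: int
    reps_failed: int
    params: dict = field(default_factory=dict)


def _cluster_sizes(cfg: SimStudyConfig) -> np.ndarray:
    lo, hi = cfg.n_range
    return np.round(np.linspace(lo, hi, cfg.I)).astype(int)


def _outlier_indices(cfg: SimStudyConfig, rng: np.random.Generator) -> np.ndarray:
    k = round(cfg.outlier_prop * cfg.I)
    if k == 0:
        return np.zeros(0, dtype=int)
    eligible = np.arange(cfg.I) if cfg.special is None else np.arange(1, cfg.I)
    return rng.choice(eligible, size=min(k, eligible.size), replace=False)


def gen_estimation_data(
    cfg: SimStudyConfig, rng: np.random.Generator | None = None
) -> tuple[ProviderTable, dict]:
    """Simulate Poisson provider summaries; returns (providers, truth).

    ``truth`` records every latent quantity (W, alpha, gamma*, outlier set,
    cluster sizes) so experiments can score estimates against it.
    """
    if cfg.family != "poisson":
        raise ValueError("gen_estimation_data generates Poisson outcomes")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = _cluster_sizes(cfg)
    W = rng.normal(0.0, 1.0, cfg.I)
    alpha = rng.normal(0.0, math.sqrt(cfg.sigma2_alpha), cfg.I)
    outliers = _outlier_indices(cfg, rng)
    gamma = np.zeros(cfg.I)
    gamma[outliers] = cfg.outlier_c + 0.5 * W[outliers]
    if cfg.special is not None:
        W[0], gamma[0] = cfg.special

    # E_i = sum_j exp(mu* + beta X_ij); one flat draw of all patients
    edges = np.concatenate(([0], np.cumsum(n)))
    X = rng.normal(cfg.x_mean, math.sqrt(cfg.x_var), int(edges[-1]))
    rates0 = np.exp(cfg.mu_star + cfg.beta * X)
    E = np.add.reduceat(rates0, edges[:-1])

    # O_i | X, alpha ~ Poisson(E_i * exp(gamma*_i + nu W_i + alpha_i)):
    # the sum of the patient-level Poisson outcomes has exactly this law.
    mult = np.exp(gamma + cfg.nu * W + alpha)
    O = rng.poisson(E * mult).astype(float)

    providers = ProviderTable(
        (
            ProviderSummary(
                id=f"P{k + 1:03d}", O=O[k], E=E[k], n_tilde=E[k], W=np.array([W[k]])
            )
            for k in range(cfg.I)
        ),
        covariate_names=["W"],
        centering_offsets=[0.0],
    )
    truth = {
        "W": W,
        "alpha": alpha,
        "gamma_star": gamma,
        "outlier_idx": outliers,
        "n": n,
        "E": E,
        "O": O,
        "nu": cfg.nu,
        "sigma2_alpha": cfg.sigma2_alpha,
    }
    return providers, truth


def gen_cre_data(
    cfg: SimStudyConfig, rng: np.random.Generator | None = None
) -> tuple[ProviderTable, dict]:
    """Simulate Normal-outcome summaries under the CRE design.

    Patient covariates X_ij ~ N(m_X_i, 0.25) with cluster means
    m_X_i ~ N(-0.4, 0.25); cluster effects gamma*_i = xi Xbar_i + tau_i
    with tau contaminated by outliers.  The expected counts are computed
    against the population norm absorbed from the underspecified
    fixed-effects fit (mu* + xi E[Xbar]), mirroring how a national model's
    intercept soaks up the average confounding effect.  The cluster-mean
    covariate Xbar_i (centered) is exposed as the W column.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = _cluster_sizes(cfg)
    m_x = rng.normal(cfg.x_mean, math.sqrt(cfg.m_x_var), cfg.I)
    # only the cluster means of X matter for the summaries we expose
    xbar = rng.normal(m_x, np.sqrt(cfg.x_var_cre / n))
    tau = rng.normal(0.0, math.sqrt(cfg.sigma2_tau), cfg.I)
    outliers = _outlier_indices(cfg, rng)
    tau[outliers] += cfg.outlier_c
    gamma = cfg.xi * xbar + tau

    # For Normal outcomes every downstream statistic uses O and E only
    # through O - E = n*(xi (Xbar - E[Xbar]) + tau) + Normal(0, n sigma2_eps)
    # (mu*, beta and the absorbed norm cancel exactly), so the expected
    # totals are normalized to a positive baseline keeping O nonnegative.
    E = 4.0 * n.astype(float)
    O = E + n * (gamma - cfg.xi * cfg.x_mean) + rng.normal(
        0.0, np.sqrt(n * cfg.sigma2_eps)
    )

    Wc = xbar - xbar.mean()
    providers = ProviderTable(
        (
            ProviderSummary(
                id=f"P{k + 1:03d}",
                O=O[k],
                E=E[k],
                n_tilde=float(n[k]),
                W=np.array([Wc[k]]),
            )
            for k in range(cfg.I)
        ),
        covariate_names=["xbar"],
        centering_offsets=[float(xbar.mean())],
    )
    truth = {
        "xbar": xbar,
        "tau": tau,
        "gamma_star": gamma,
        "outlier_idx": outliers,
        "n": n,
        "xi": cfg.xi,
        "sigma2_tau": cfg.sigma2_tau,
    }
    return providers, truth


def _aggregate_estimates(est: np.ndarray, true_value: float) -> dict:
    est = np.asarray(est, dtype=float)
    R = est.size
    bias = float(est.mean() - true_value)
    out = {
        "bias": bias,
        "abs_bias": abs(bias),
        "mse": float(np.mean((est - true_value) ** 2)),
        "sd": float(est.std(ddof=1)) if R > 1 else float("nan"),
    }
    out["mc_se"] = out["sd"] / math.sqrt(R) if R > 1 else float("nan")
    return out


def _family(cfg: SimStudyConfig) -> FamilySpec:
    if cfg.family == "normal":
        return FamilySpec("normal", cfg.sigma2_eps)
    return FamilySpec(cfg.family)


def _run_paired_fits(cfg: SimStudyConfig, generator, true_nu: float, true_s2: float,
                     design: str) -> SimStudyResult:
    fam = _family(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.reps)
    rows = {"rppclc": {"nu": [], "s2": [], "se": []}, "mle": {"nu": [], "s2": []}}
    failed = 0
    for ss in children:
        rng = np.random.default_rng(ss)
        providers, _ = generator(cfg, rng)
        try:
            fit_r = fit_rppclc(providers, fam, c=cfg.interval_c)
            fit_m = fit_normal_mle(providers, fam)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        rows["rppclc"]["nu"].append(fit_r.nu_hat[0])
        rows["rppclc"]["s2"].append(fit_r.sigma2_alpha_hat)
        rows["rppclc"]["se"].append(
            math.sqrt(fit_r.cov_nu[0, 0]) if fit_r.cov_nu is not None else np.nan
        )
        rows["mle"]["nu"].append(fit_m.nu_hat[0])
        rows["mle"]["s2"].append(fit_m.sigma2_alpha_hat)
    metrics, mc_se = {}, {}
    for key in ("rppclc", "mle"):
        if not rows[key]["nu"]:
            continue
        agg_nu = _aggregate_estimates(np.array(rows[key]["nu"]), true_nu)
        agg_s2 = _aggregate_estimates(np.array(rows[key]["s2"]), true_s2)
        metrics[key] = {
            "bias_nu": agg_nu["bias"],
            "abs_bias_nu": agg_nu["abs_bias"],
            "mse_nu": agg_nu["mse"],
            "sd_nu": agg_nu["sd"],
            "bias_sigma2": agg_s2["bias"],
            "abs_bias_sigma2": agg_s2["abs_bias"],
            "mse_sigma2": agg_s2["mse"],
        }
        mc_se[key] = {"nu": agg_nu["mc_se"], "sigma2": agg_s2["mc_se"]}
    if rows["rppclc"]["se"]:
        metrics["rppclc"]["mean_reported_se_nu"] = float(
            np.nanmean(rows["rppclc"]["se"])
        )
    return SimStudyResult(
        design=design,
        metrics=metrics,
        mc_se=mc_se,
        reps_completed=cfg.reps - failed,
        reps_failed=failed,
        params={"outlier_prop": cfg.outlier_prop, "outlier_c": cfg.outlier_c},
    )


def run_estimation_study(cfg: SimStudyConfig) -> SimStudyResult:
    """Bias/MSE of (nu_hat, sigma2_alpha_hat) for the robust fit vs normal MLE."""
    return _run_paired_fits(
        cfg, gen_estimation_data, cfg.nu, cfg.sigma2_alpha, "estimation"
    )


def run_cre_study(cfg: SimStudyConfig) -> SimStudyResult:
    """Bias/MSE of xi_hat under the CRE design (Normal outcomes)."""
    cre_cfg = replace(cfg, family="normal")
    return _run_paired_fits(
        cre_cfg, gen_cre_data, cre_cfg.xi, cre_cfg.sigma2_tau, "cre"
    )


def _evaluate_special_provider(
    providers: Sequence[ProviderSummary],
    cfg: SimStudyConfig,
    fam: FamilySpec,
) -> dict | None:
    """Flags and interval coverage for provider 1 under all four rules."""
    p1 = providers[0]
    z = zscores(providers, fam)
    z1 = float(z[0])

    if cfg.use_true_params:
        nu_hat = np.array([cfg.nu])
        s2_hat = cfg.sigma2_alpha
        cov_nu = np.zeros((1, 1))
    else:
        fit = fit_rppclc(providers, fam, c=cfg.interval_c)
        nu_hat, s2_hat, cov_nu = fit.nu_hat, fit.sigma2_alpha_hat, fit.cov_nu
        if cov_nu is None:
            return None

    m1 = null_moments(p1, fam, nu_hat, s2_hat)
    z1_star = corrected_z(z1, m1)

    pn = posterior_nu(nu_hat, cov_nu, cfg.prior_var * np.eye(nu_hat.size))
    lp = lambda_posterior(p1, pn, s2_hat)
    rp_adj = RStarPosterior(
        p1.O, p1.E, mu_log=lp.mu_log, s2_log=lp.s2_log, n_nodes=cfg.n_nodes
    )
    rp_nai = naive_posterior(p1)

    lo_n, hi_n, flag_n = flag_bayes(rp_nai, cfg.level)
    lo_a, hi_a, flag_a = flag_bayes(rp_adj, cfg.level)
    true_ratio = math.exp(cfg.special[1]) if cfg.special else 1.0
    return {
        "flag_freq_naive": flag_frequentist(z1, cfg.threshold) != "null",
        "flag_freq_adjusted": flag_frequentist(z1_star, cfg.threshold) != "null",
        "flag_bayes_naive": flag_n != "null",
        "flag_bayes_adjusted": flag_a != "null",
        "cover_naive": lo_n <= true_ratio <= hi_n,
        "cover_adjusted": lo_a <= true_ratio <= hi_a,
    }


def run_inference_study(cfg: SimStudyConfig) -> SimStudyResult:
    """Flag rates and interval coverage for the pinned special provider.

    When gamma*_1 = 0 the flag rate is a false-flagging probability (FFP);
    otherwise it is a true-flagging probability (TFP).  Coverage is the
    fraction of credible intervals containing the true measure value
    exp(gamma*_1).
    """
    if cfg.special is None:
        raise ValueError("inference studies require cfg.special = (W_1, gamma*_1)")
    fam = _family(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.reps)
    records = []
    failed = 0
    for ss in children:
        rng = np.random.default_rng(ss)
        providers, _ = gen_estimation_data(cfg, rng)
        try:
            rec = _evaluate_special_provider(providers, cfg, fam)
        except (ValueError, np.linalg.LinAlgError, FloatingPointError):
            rec = None
        if rec is None:
            failed += 1
            continue
        records.append(rec)
    if not records:
        raise RuntimeError("all replicates failed in the inference study")
    df = pd.DataFrame.from_records(records)
    rates = df.mean(axis=0).to_dict()
    R = len(df)
    mc_se = {k: math.sqrt(max(v * (1 - v), 0.0) / R) for k, v in rates.items()}
    is_null = cfg.special[1] == 0.0
    metrics = {("ffp" if is_null else "tfp"): {
        k.removeprefix("flag_"): rates[k] for k in rates if k.startswith("flag_")
    }}
    metrics["coverage"] = {
        "naive": rates["cover_naive"],
        "adjusted": rates["cover_adjusted"],
    }
    return SimStudyResult(
        design="inference",
        metrics=metrics,
        mc_se=mc_se,
        reps_completed=R,
        reps_failed=failed,
        params={"W1": cfg.special[0], "gamma1": cfg.special[1],
                "use_true_params": cfg.use_true_params},
    )


def run_coverage_table(
    cfg: SimStudyConfig, gamma_grid: Sequence[float]
) -> pd.DataFrame:
    """Empirical coverage of naive vs adjusted credible intervals over a
    grid of true quality effects gamma*_1 (the special provider has W_1
    fixed from ``cfg.special``)."""
    if cfg.special is None:
        raise ValueError("coverage table requires cfg.special to pin W_1")
    w1 = cfg.special[0]
    rows = []
    for k, g in enumerate(gamma_grid):
        sub = replace(cfg, special=(w1, float(g)), seed=cfg.seed + k)
        res = run_inference_study(sub)
        rows.append(
            {
                "gamma": float(g),
                "coverage_naive": res.metrics["coverage"]["naive"],
                "coverage_adjusted": res.metrics["coverage"]["adjusted"],
                "mc_se_naive": res.mc_se["cover_naive"],
                "mc_se_adjusted": res.mc_se["cover_adjusted"],
                "reps": res.reps_completed,
            }
        )
    return pd.DataFrame(rows)
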