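"""Outlier flagging: corrected Z-scores and the measure-ratio posterior.

Two inference routes are supported.

Frequentist: standardize each naive Z-score by its fitted null moments,

    z* = (z - E[Z | W, null]) / sqrt(Var[Z | W, null]),

and flag when |z*| exceeds a threshold (default 1.96).

Pseudo-Bayesian: treat nu as random with a multivariate normal prior,
combine with the asymptotic normality of nu_hat to get a normal posterior,
propagate through the total confounding factor Lambda = exp(W'nu + alpha)
(approximately Lognormal, with sigma2_alpha plugged in as known), and
correct the conventional Gamma(O+2, E+2) posterior for the measure ratio R
to a corrected ratio R* whose posterior is the Lognormal mixture of
Gamma(O+2, E*lambda+2) densities.  Providers are flagged when the
equal-tailed credible interval excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammainc, gammaln
from numpy.polynomial.hermite import hermgauss

from .data_model import NullMoments, ProviderSummary, ZScore

__all__ = [
    "PosteriorNu",
    "LambdaPosterior",
    "RStarPosterior",
    "corrected_z",
    "flag_frequentist",
    "posterior_nu",
    "lambda_posterior",
    "rstar_posterior",
    "naive_posterior",
    "flag_bayes",
]


def corrected_z(z: ZScore | float, m: NullMoments) -> float:
    """Standardize a naive Z-score by its fitted null mean and variance."""
    zval = z.z if isinstance(z, ZScore) else float(z)
    if not m.var > 0:
        raise ValueError("null variance must be positive")
    return (zval - m.mean) / np.sqrt(m.var)


def flag_frequentist(z_star: float, threshold: float = 1.96) -> str:
    """Two-sided flag; 'low' means below-norm outcomes (e.g. under-transplanting).

    The comparison is strict: a score exactly at the threshold is 'null'.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if z_star < -threshold:
        return "low"
    if z_star > threshold:
        return "high"
    return "null"


@dataclass
class PosteriorNu:
    """Normal posterior of the observed-confounding effects nu."""

    m_post: np.ndarray
    Sigma_post: np.ndarray
    Sigma_prior: np.ndarray


def posterior_nu(
    nu_hat: np.ndarray, Sigma_nu_hat: np.ndarray, Sigma_prior: np.ndarray
) -> PosteriorNu:
    """Conjugate-normal update of nu given its sampling covariance.

    m_post = Sigma_prior (Sigma_prior + Sigma_nu_hat)^-1 nu_hat and
    Sigma_post = Sigma_prior - Sigma_prior (Sigma_prior + Sigma_nu_hat)^-1
    Sigma_prior (the form that stays valid when Sigma_nu_hat is singular).
    """
    nu_hat = np.atleast_1d(np.asarray(nu_hat, dtype=float))
    Sp = np.atleast_2d(np.asarray(Sigma_prior, dtype=float))
    Sn = np.atleast_2d(np.asarray(Sigma_nu_hat, dtype=float))
    total = Sp + Sn
    try:
        gain = np.linalg.solve(total, Sp).T  # Sp (Sp+Sn)^-1
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "Sigma_prior + Sigma_nu_hat is singular; add prior regularization "
            "(a positive-definite Sigma_prior)"
        ) from err
    m_post = gain @ nu_hat
    Sigma_post = Sp - gain @ Sp
    Sigma_post = (Sigma_post + Sigma_post.T) / 2.0
    return PosteriorNu(m_post=m_post, Sigma_post=Sigma_post, Sigma_prior=Sp)


@dataclass(frozen=True)
class LambdaPosterior:
    """Lognormal posterior parameters of the total confounding factor.

    Lambda = exp(W'nu + alpha) with log-scale mean ``mu_log = W'm_post`` and
    variance ``s2_log = W' Sigma_post W + sigma2_alpha`` (the unobserved
    component enters as a known variance).
    """

    mu_log: float
    s2_log: float

    def __post_init__(self) -> None:
        if self.s2_log < 0:
            raise ValueError("s2_log must be >= 0")


def lambda_posterior(
    p: ProviderSummary, pn: PosteriorNu, sigma2_alpha: float
) -> LambdaPosterior:
    """Per-provider Lognormal posterior of Lambda_i = exp(W_i'nu + alpha_i)."""
    if sigma2_alpha < 0:
        raise ValueError("sigma2_alpha must be >= 0")
    W = p.W
    mu = float(W @ pn.m_post) if W.size else 0.0
    s2 = float(W @ pn.Sigma_post @ W) if W.size else 0.0
    return LambdaPosterior(mu_log=mu, s2_log=s2 + sigma2_alpha)


class RStarPosterior:
    """Posterior of the corrected measure ratio R*.

    A mixture of Gamma(O+2, E*lambda+2) distributions over the Lognormal
    posterior of lambda, integrated with Gauss–Hermite quadrature (64 nodes
    by default) so the result is deterministic.  With ``s2_log = 0`` the
    mixture collapses to a single Gamma — in particular the conventional
    uncorrected posterior Gamma(O+2, E+2) at ``mu_log = 0``.
    """

    def __init__(
        self,
        O: float,
        E: float,
        mu_log: float = 0.0,
        s2_log: float = 0.0,
        n_nodes: int = 64,
        id: str | None = None,
    ) -> None:
        if O < 0 or not E > 0:
            raise ValueError("need O >= 0 and E > 0")
        if s2_log < 0:
            raise ValueError("s2_log must be >= 0")
        self.id = id
        self.O = float(O)
        self.E = float(E)
        self.mu_log = float(mu_log)
        self.s2_log = float(s2_log)
        self.shape = self.O + 2.0
        if s2_log == 0.0:
            self.lambdas = np.array([np.exp(mu_log)])
            self.weights = np.array([1.0])
        else:
            x, w = hermgauss(n_nodes)
            self.lambdas = np.exp(mu_log + np.sqrt(2.0 * s2_log) * x)
            self.weights = w / np.sqrt(np.pi)
        self.rates = self.E * self.lambdas + 2.0
        if not np.all(np.isfinite(self.rates)):
            raise FloatingPointError("non-finite quadrature rates in R* posterior")
        self._median: float | None = None

    def pdf(self, r):
        """Mixture density of R* at r (vectorized)."""
        r = np.asarray(r, dtype=float)
        rr = np.atleast_1d(r)[:, None]
        a = self.shape
        with np.errstate(divide="ignore", invalid="ignore"):
            logpdf = (
                a * np.log(self.rates)[None, :]
                - gammaln(a)
                + (a - 1.0) * np.log(rr)
                - rr * self.rates[None, :]
            )
            dens = np.where(rr > 0, np.exp(logpdf), 0.0)
        out = dens @ self.weights
        return out if r.ndim else float(out[0])

    def cdf(self, r):
        """Mixture CDF of R* at r (vectorized)."""
        r = np.asarray(r, dtype=float)
        rr = np.clip(np.atleast_1d(r)[:, None], 0.0, None)
        out = gammainc(self.shape, rr * self.rates[None, :]) @ self.weights
        return out if r.ndim else float(out[0])

    def ppf(self, q: float) -> float:
        """Quantile by monotone root-finding on the mixture CDF."""
        if not 0.0 < q < 1.0:
            raise ValueError("quantile level must be in (0, 1)")
        lo = 1e-300
        hi = (self.shape + 10.0 * np.sqrt(self.shape)) / np.min(self.rates)
        while self.cdf(hi) < q:
            hi *= 2.0
            if hi > 1e12:
                raise FloatingPointError("failed to bracket the quantile")
        return float(brentq(lambda r: self.cdf(r) - q, lo, hi, xtol=1e-12, rtol=1e-12))

    def mean(self) -> float:
        """Posterior mean: mixture of Gamma means (O+2)/(E*lambda+2)."""
        return float(np.sum(self.weights * self.shape / self.rates))

    def median(self) -> float:
        if self._median is None:
            self._median = self.ppf(0.5)
        return self._median


def rstar_posterior(
    p: ProviderSummary, lp: LambdaPosterior, n_nodes: int = 64
) -> RStarPosterior:
    """Corrected measure-ratio posterior for one provider."""
    return RStarPosterior(
        p.O, p.E, mu_log=lp.mu_log, s2_log=lp.s2_log, n_nodes=n_nodes, id=p.id
    )


def naive_posterior(p: ProviderSummary) -> RStarPosterior:
    """Conventional uncorrected Gamma(O+2, E+2) posterior of the ratio R."""
    return RStarPosterior(p.O, p.E, mu_log=0.0, s2_log=0.0, id=p.id)


def flag_bayes(
    rp: RStarPosterior, level: float = 0.95
) -> tuple[float, float, str]:
    """Equal-tailed credible interval and flag against the null ratio 1."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lo = rp.ppf(tail)
    hi = rp.ppf(1.0 - tail)
    if hi < 1.0:
        flag = "low"
    elif lo > 1.0:
        flag = "high"
    else:
        flag = "null"
    return lo, hi, flag
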