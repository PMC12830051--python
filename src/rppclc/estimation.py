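"""Robust empirical-null estimation of (nu, sigma2_alpha, pi0).

The estimator treats the naive Z-scores as (asymptotically) normal with the
family-specific null moments, but acknowledges that an unknown subset of
providers are genuine outliers.  A per-provider null interval [A_i, B_i] is
specified; outlying providers are assumed to land outside their interval
with probability one, so providers inside contribute a (weighted) normal
density and providers outside contribute only the exceedance probability
1 - pi0 * Q_i, where Q_i is the normal mass of [A_i, B_i].  The likelihood

    L(nu, sigma2_alpha, pi0) =
        prod_{i in S0} pi0 * phi_i(z_i) * prod_{i not in S0} (1 - pi0 * Q_i)

is maximized numerically.  The non-robust baseline ("normal MLE") drops the
truncation entirely and fits the plain normal likelihood to all providers.

Initialization is itself robust: a Huber regression of z on the approximate
mean design sqrt(n_tilde/a_psi) * W, and a median-of-moments start for
sigma2_alpha.  Null intervals are centered at the initial fit's moments and
refined once at the first optimum (toggleable), which keeps the two-stage
estimator deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .data_model import ProviderSummary, stack_providers
from .families import FamilySpec
from .null_moments import moment_arrays, zscores

__all__ = [
    "NullIntervals",
    "ENFit",
    "init_params",
    "make_null_intervals",
    "en_negloglik",
    "fit_rppclc",
    "fit_normal_mle",
    "sandwich_cov",
]

_LOG_FLOOR = np.log(1e-300)
_PI0_LO = 1e-4
_SIGMA2_LO, _SIGMA2_HI = 1e-10, 1e3
_HUBER_T = 1.345


@dataclass(frozen=True)
class NullIntervals:
    """Per-provider null region [A_i, B_i] on the Z scale."""

    A: np.ndarray
    B: np.ndarray
    c: float

    def __post_init__(self) -> None:
        if not np.all(self.A < self.B):
            raise ValueError("null intervals require A_i < B_i for every provider")

    def null_mask(self, z: np.ndarray) -> np.ndarray:
        return (z >= self.A) & (z <= self.B)


@dataclass
class ENFit:
    """Fitted empirical-null parameters and diagnostics."""

    nu_hat: np.ndarray
    sigma2_alpha_hat: float
    pi0_hat: float
    null_set: list
    intervals: NullIntervals | None
    cov_nu: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    method: str = "rppclc"
    message: str = ""
    nu_init: np.ndarray | None = None

    @property
    def n_null(self) -> int:
        return len(self.null_set)


def _design(n_tilde: np.ndarray, W: np.ndarray, a_psi: float) -> np.ndarray:
    """Rows sqrt(n_tilde/a_psi) * W_i of the approximate-mean design."""
    return np.sqrt(n_tilde / a_psi)[:, None] * W


def init_params(
    z: np.ndarray,
    providers: Sequence[ProviderSummary],
    fam: FamilySpec,
) -> tuple[np.ndarray, float, float]:
    """Robust initial values (nu0, sigma2_0, pi0_0).

    nu0 comes from a Huber M-regression (tuning 1.345) of z on the
    approximate null-mean design through the origin; sigma2_0 from a
    median-of-moments inversion of Var[Z] = 1 + (sigma2/a_psi) n_tilde on
    the residuals; pi0_0 = 0.95.
    """
    z = np.asarray(z, dtype=float)
    _, _, _, n_tilde, W, _ = stack_providers(providers)
    P = W.shape[1]
    if len(providers) < P + 2:
        raise ValueError(f"need at least P+2={P + 2} providers, got {len(providers)}")
    X = _design(n_tilde, W, fam.a_psi)
    if P == 0 or not np.any(X):
        nu0 = np.zeros(P)
    else:
        if np.linalg.matrix_rank(X) < P:
            keep = [k for k in range(P) if np.any(X[:, k])]
            raise ValueError(
                f"rank-deficient covariate design (rank < {P}); "
                f"columns with any signal: {keep}"
            )
        rlm = sm.RLM(z, X, M=sm.robust.norms.HuberT(t=_HUBER_T))
        nu0 = np.asarray(rlm.fit().params, dtype=float)
    r = z - X @ nu0 if P else z.copy()
    sigma2_0 = float(np.median(np.clip((r**2 - 1.0) / n_tilde, 0.0, None)) * fam.a_psi)
    return nu0, sigma2_0, 0.95


def make_null_intervals(
    z: np.ndarray,
    mean0: np.ndarray,
    var0: np.ndarray,
    c: float = 2.5,
) -> NullIntervals:
    """Null intervals mean0_i +/- c * sqrt(var0_i); c = inf disables truncation."""
    if not c > 0:
        raise ValueError(f"interval half-width c must be positive, got {c}")
    sd = np.sqrt(var0)
    if np.isinf(c):
        A = np.full_like(mean0, -np.inf)
        B = np.full_like(mean0, np.inf)
    else:
        A = mean0 - c * sd
        B = mean0 + c * sd
    return NullIntervals(A=A, B=B, c=float(c))


def _negloglik_arrays(
    nu: np.ndarray,
    sigma2: float,
    pi0: float,
    z: np.ndarray,
    n_tilde: np.ndarray,
    W: np.ndarray,
    sum_b3: np.ndarray | None,
    in_null: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    fam: FamilySpec,
) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean, var = moment_arrays(n_tilde, W, nu, sigma2, fam, sum_b3)
    sd = np.sqrt(var)
    ll = 0.0
    if np.any(in_null):
        m, v, zz = mean[in_null], var[in_null], z[in_null]
        ll += np.sum(
            np.log(pi0) - 0.5 * np.log(2.0 * np.pi * v) - (zz - m) ** 2 / (2.0 * v)
        )
    out = ~in_null
    if np.any(out):
        hi = ndtr((B[out] - mean[out]) / sd[out])
        lo = ndtr((A[out] - mean[out]) / sd[out])
        q = np.clip(hi - lo, 0.0, 1.0)
        ll += np.sum(np.maximum(np.log1p(-pi0 * q), _LOG_FLOOR))
    # keep the optimizer's finite-difference probes well defined
    return -ll if np.isfinite(ll) else -_LOG_FLOOR * len(z)


def en_negloglik(
    theta: tuple,
    z: np.ndarray,
    providers: Sequence[ProviderSummary],
    intervals: NullIntervals,
    fam: FamilySpec,
) -> float:
    """Negative log of the truncated-normal empirical-null likelihood."""
    nu, sigma2, pi0 = theta
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    if sigma2 < 0:
        raise ValueError(f"sigma2_alpha must be >= 0, got {sigma2}")
    if not (0.0 < pi0 <= 1.0):
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    z = np.asarray(z, dtype=float)
    _, _, _, n_tilde, W, sum_b3 = stack_providers(providers)
    in_null = intervals.null_mask(z)
    return _negloglik_arrays(
        nu, sigma2, pi0, z, n_tilde, W, sum_b3, in_null, intervals.A, intervals.B, fam
    )


def _pack(nu, sigma2, pi0, fix_sigma2, fix_pi0):
    x = list(np.atleast_1d(nu))
    if fix_sigma2 is None:
        x.append(np.log(np.clip(sigma2, _SIGMA2_LO, _SIGMA2_HI)))
    if fix_pi0 is None:
        frac = np.clip((pi0 - _PI0_LO) / (1.0 - _PI0_LO), 1e-9, 1.0 - 1e-9)
        x.append(logit(frac))
    return np.asarray(x, dtype=float)


def _unpack(x, P, fix_sigma2, fix_pi0):
    nu = x[:P]
    k = P
    if fix_sigma2 is None:
        sigma2 = float(np.exp(np.clip(x[k], np.log(_SIGMA2_LO), np.log(_SIGMA2_HI))))
        k += 1
    else:
        sigma2 = float(fix_sigma2)
    if fix_pi0 is None:
        pi0 = float(_PI0_LO + (1.0 - _PI0_LO) * expit(x[k]))
    else:
        pi0 = float(fix_pi0)
    return nu, sigma2, pi0


def _maximize(
    z, n_tilde, W, sum_b3, in_null, A, B, fam, start, fix_sigma2, fix_pi0, tol, maxiter
):
    P = W.shape[1]

    def objective(x):
        nu, sigma2, pi0 = _unpack(x, P, fix_sigma2, fix_pi0)
        return _negloglik_arrays(
            nu, sigma2, pi0, z, n_tilde, W, sum_b3, in_null, A, B, fam
        )

    x0 = _pack(*start, fix_sigma2, fix_pi0)
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"ftol": tol, "gtol": 1e-10, "maxiter": maxiter},
    )
    nu, sigma2, pi0 = _unpack(res.x, P, fix_sigma2, fix_pi0)
    return nu, sigma2, pi0, res


def sandwich_cov(
    nu: np.ndarray,
    sigma2_alpha: float,
    providers: Sequence[ProviderSummary],
    fam: FamilySpec,
    null_mask: np.ndarray,
) -> np.ndarray:
    """Sandwich covariance of nu_hat over the null providers.

    Sigma = (X'X)^-1 X' Omega X (X'X)^-1 with X rows sqrt(n_tilde/a_psi)*W_i
    restricted to the null set and Omega the diagonal of fitted null
    variances Var[Z_i | W_i, null].
    """
    _, _, _, n_tilde, W, sum_b3 = stack_providers(providers)
    P = W.shape[1]
    if int(np.sum(null_mask)) < P:
        raise ValueError(
            f"null set has {int(np.sum(null_mask))} members; need at least P={P}"
        )
    X = _design(n_tilde, W, fam.a_psi)[null_mask]
    _, var = moment_arrays(
        n_tilde[null_mask],
        W[null_mask],
        nu,
        sigma2_alpha,
        fam,
        None if sum_b3 is None else sum_b3[null_mask],
    )
    xtx = X.T @ X
    bread = np.linalg.pinv(xtx)
    meat = X.T @ (var[:, None] * X)
    cov = bread @ meat @ bread
    return (cov + cov.T) / 2.0


def _fit(
    providers: Sequence[ProviderSummary],
    fam: FamilySpec,
    *,
    c: float,
    refine: bool,
    fix_sigma2: float | None,
    fix_pi0: float | None,
    tol: float,
    maxiter: int,
    method: str,
) -> ENFit:
    ids, _, _, n_tilde, W, sum_b3 = stack_providers(providers)
    z = zscores(providers, fam)
    P = W.shape[1]
    nu0, s20, pi00 = init_params(z, providers, fam)
    if fix_sigma2 is not None:
        s20 = fix_sigma2
    if fix_pi0 is not None:
        pi00 = fix_pi0

    mean0, var0 = moment_arrays(n_tilde, W, nu0, s20, fam, sum_b3)
    intervals = make_null_intervals(z, mean0, var0, c)
    in_null = intervals.null_mask(z)
    if int(in_null.sum()) < max(P, 1):
        raise ValueError(
            f"only {int(in_null.sum())} providers fall in their null intervals; "
            f"need at least {max(P, 1)} — widen c or check the inputs"
        )

    start = (nu0, s20, pi00)
    nu, s2, pi0, res = _maximize(
        z, n_tilde, W, sum_b3, in_null, intervals.A, intervals.B, fam,
        start, fix_sigma2, fix_pi0, tol, maxiter,
    )
    n_iter = int(res.nit)
    converged = bool(res.success)

    if refine and not np.isinf(c):
        mean1, var1 = moment_arrays(n_tilde, W, nu, s2, fam, sum_b3)
        intervals = make_null_intervals(z, mean1, var1, c)
        in_null = intervals.null_mask(z)
        if int(in_null.sum()) >= max(P, 1):
            nu, s2, pi0, res = _maximize(
                z, n_tilde, W, sum_b3, in_null, intervals.A, intervals.B, fam,
                (nu, s2, pi0), fix_sigma2, fix_pi0, tol, maxiter,
            )
            n_iter += int(res.nit)
            converged = bool(res.success)

    null_ids = [ids[k] for k in np.flatnonzero(in_null)]
    cov = None
    if P and int(in_null.sum()) >= P:
        cov = sandwich_cov(nu, s2, providers, fam, in_null)
    elif P == 0:
        cov = np.zeros((0, 0))
    return ENFit(
        nu_hat=np.atleast_1d(nu),
        sigma2_alpha_hat=float(s2),
        pi0_hat=float(pi0),
        null_set=null_ids,
        intervals=intervals,
        cov_nu=cov,
        loglik=float(-res.fun),
        converged=converged,
        n_iter=n_iter,
        method=method,
        message=str(res.message),
        nu_init=np.atleast_1d(nu0),
    )


def fit_rppclc(
    providers: Sequence[ProviderSummary],
    fam: FamilySpec,
    c: float = 2.5,
    *,
    refine: bool = True,
    fix_sigma2: float | None = None,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> ENFit:
    """Fit the robust privacy-preserving cluster-level confounding model.

    Non-convergence of the optimizer is reported through ``converged`` and
    ``message`` on the returned fit rather than raised.
    """
    return _fit(
        providers, fam, c=c, refine=refine, fix_sigma2=fix_sigma2, fix_pi0=None,
        tol=tol, maxiter=maxiter, method="rppclc",
    )


def fit_normal_mle(
    providers: Sequence[ProviderSummary],
    fam: FamilySpec,
    *,
    fix_sigma2: float | None = None,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> ENFit:
    """Non-robust baseline: plain normal MLE over all providers (pi0 = 1).

    For the Normal family with sigma2_alpha fixed at zero this coincides
    with ordinary least squares on the null-mean design.
    """
    return _fit(
        providers, fam, c=np.inf, refine=False, fix_sigma2=fix_sigma2, fix_pi0=1.0,
        tol=tol, maxiter=maxiter, method="normal_mle",
    )
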