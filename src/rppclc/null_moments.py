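"""Naive Z-scores and their conditional null moments under each family.

The naive score statistic for provider ``i`` is

    Z_i = (O_i - E_i) / sqrt(a(psi) * n_tilde_i),

which only adjusts for patient-level case mix.  Under the null (no true
quality deviation) its conditional mean and variance given the observed
cluster covariates ``W_i`` are driven by the confounding effects ``nu`` and
the unobserved-confounding variance ``sigma2_alpha``:

* Normal outcomes (exact):
      mean = sqrt(n/sigma2_eps) * W'nu,   var = 1 + (sigma2_alpha/sigma2_eps) * n
* Poisson outcomes (exact, canonical log link), with
  x = W'nu + sigma2_alpha/2:
      mean = sqrt(n_tilde) * (exp(x) - 1)
      var  = exp(x) * [1 + exp(x) * (exp(sigma2_alpha) - 1) * n_tilde]
  For quasi-Poisson (a_psi != 1) the statistic is already standardized by
  sqrt(a_psi * n_tilde), so the mean is divided by sqrt(a_psi) and the
  variance by a_psi; at a_psi = 1 this reduces to the exact Poisson case.
* General exponential family (first-order approximation):
      mean ~ sqrt(n_tilde/a_psi) * W'nu
      var  ~ 1 + (sum_b3/n_tilde) * W'nu + (sigma2_alpha/a_psi) * n_tilde
"""

from __future__ import annotations

import warnings

import numpy as np

from .data_model import NullMoments, ProviderSummary, ZScore
from .families import FamilySpec

__all__ = [
    "compute_z",
    "zscores",
    "null_moments_poisson",
    "null_moments_normal",
    "null_moments_general",
    "null_moments",
    "moment_arrays",
]

#: floor applied to the general-family variance approximation
VAR_FLOOR = 1e-6

#: clip on the exponent W'nu + sigma2/2 to keep the Poisson moments finite
_EXP_CLIP = 50.0


def compute_z(p: ProviderSummary, fam: FamilySpec) -> ZScore:
    """Naive fixed-effects score statistic ``(O - E)/sqrt(a_psi * n_tilde)``."""
    return ZScore(id=p.id, z=(p.O - p.E) / np.sqrt(fam.a_psi * p.n_tilde))


def zscores(providers, fam: FamilySpec) -> np.ndarray:
    """Vector of naive Z-scores for a provider table."""
    O = np.array([p.O for p in providers], dtype=float)
    E = np.array([p.E for p in providers], dtype=float)
    n = np.array([p.n_tilde for p in providers], dtype=float)
    return (O - E) / np.sqrt(fam.a_psi * n)


def _check_sigma2(sigma2_alpha: float) -> None:
    if sigma2_alpha < 0:
        raise ValueError(f"sigma2_alpha must be >= 0, got {sigma2_alpha}")


def _poisson_arrays(
    n_tilde: np.ndarray, weta: np.ndarray, sigma2_alpha: float, a_psi: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    x = np.clip(weta + sigma2_alpha / 2.0, -_EXP_CLIP, _EXP_CLIP)
    ex = np.exp(x)
    mean = np.sqrt(n_tilde) * (ex - 1.0) / np.sqrt(a_psi)
    var = ex * (1.0 + ex * np.expm1(sigma2_alpha) * n_tilde) / a_psi
    return mean, var


def _general_arrays(
    n_tilde: np.ndarray,
    weta: np.ndarray,
    sigma2_alpha: float,
    a_psi: float,
    sum_b3: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    mean = np.sqrt(n_tilde / a_psi) * weta
    var = 1.0 + (sum_b3 / n_tilde) * weta + (sigma2_alpha / a_psi) * n_tilde
    if np.any(var < VAR_FLOOR):
        warnings.warn(
            "general-family variance approximation went nonpositive; "
            f"clamping to {VAR_FLOOR}",
            RuntimeWarning,
            stacklevel=2,
        )
        var = np.maximum(var, VAR_FLOOR)
    return mean, var


def moment_arrays(
    n_tilde: np.ndarray,
    W: np.ndarray,
    nu: np.ndarray,
    sigma2_alpha: float,
    fam: FamilySpec,
    sum_b3: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized null mean/variance for a whole provider table."""
    _check_sigma2(sigma2_alpha)
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    weta = W @ nu if W.size else np.zeros(len(n_tilde))
    if fam.family == "poisson":
        return _poisson_arrays(n_tilde, weta, sigma2_alpha, fam.a_psi)
    if fam.family == "normal":
        mean = np.sqrt(n_tilde / fam.a_psi) * weta
        var = 1.0 + (sigma2_alpha / fam.a_psi) * n_tilde
        return mean, var
    if sum_b3 is None:
        raise ValueError("general family requires sum_b3 for every provider")
    return _general_arrays(n_tilde, weta, sigma2_alpha, fam.a_psi, sum_b3)


def null_moments_poisson(
    p: ProviderSummary, nu, sigma2_alpha: float, a_psi: float = 1.0
) -> NullMoments:
    """Exact Poisson null moments of the naive Z-score (canonical log link)."""
    _check_sigma2(sigma2_alpha)
    weta = float(p.W @ np.atleast_1d(np.asarray(nu, dtype=float)))
    mean, var = _poisson_arrays(
        np.array([p.n_tilde]), np.array([weta]), sigma2_alpha, a_psi
    )
    return NullMoments(id=p.id, mean=float(mean[0]), var=float(var[0]))


def null_moments_normal(
    p: ProviderSummary, nu, sigma2_alpha: float, sigma2_eps: float = 1.0
) -> NullMoments:
    """Exact Normal-outcome null moments (heteroskedastic linear model)."""
    _check_sigma2(sigma2_alpha)
    weta = float(p.W @ np.atleast_1d(np.asarray(nu, dtype=float)))
    mean = np.sqrt(p.n_tilde / sigma2_eps) * weta
    var = 1.0 + (sigma2_alpha / sigma2_eps) * p.n_tilde
    return NullMoments(id=p.id, mean=mean, var=var)


def null_moments_general(
    p: ProviderSummary, nu, sigma2_alpha: float, a_psi: float = 1.0
) -> NullMoments:
    """First-order null moments for an arbitrary exponential family."""
    _check_sigma2(sigma2_alpha)
    if p.sum_b3 is None:
        raise ValueError(f"provider {p.id!r}: sum_b3 required for general family")
    weta = float(p.W @ np.atleast_1d(np.asarray(nu, dtype=float)))
    mean, var = _general_arrays(
        np.array([p.n_tilde]),
        np.array([weta]),
        sigma2_alpha,
        a_psi,
        np.array([p.sum_b3]),
    )
    return NullMoments(id=p.id, mean=float(mean[0]), var=float(var[0]))


def null_moments(
    p: ProviderSummary, fam: FamilySpec, nu, sigma2_alpha: float
) -> NullMoments:
    """Family dispatcher for the per-provider null moments."""
    if fam.family == "poisson":
        return null_moments_poisson(p, nu, sigma2_alpha, fam.a_psi)
    if fam.family == "normal":
        return null_moments_normal(p, nu, sigma2_alpha, fam.a_psi)
    return null_moments_general(p, nu, sigma2_alpha, fam.a_psi)
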