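"""Naive vs confounding-adjusted posterior for one center's measure ratio.

A center in a region with abundant resources (W = 1, confounding effect
nu = 0.5) observes more events than its case-mix-expected count.  The
conventional Gamma(O+2, E+2) posterior credits the center; the corrected
posterior divides out the Lognormal confounding factor Lambda =
exp(W'nu + alpha) and widens for the overdispersion sigma2_alpha.
"""

import numpy as np

from rppclc import (
    PosteriorNu,
    ProviderSummary,
    flag_bayes,
    lambda_posterior,
    naive_posterior,
    rstar_posterior,
)

center = ProviderSummary(id="C001", O=130.0, E=100.0, n_tilde=100.0, W=[1.0])

# fitted confounding model (illustrative values)
pn = PosteriorNu(
    m_post=np.array([0.5]),
    Sigma_post=np.array([[0.01]]),
    Sigma_prior=100.0 * np.eye(1),
)
sigma2_alpha = 0.05

naive = naive_posterior(center)
adjusted = rstar_posterior(center, lambda_posterior(center, pn, sigma2_alpha))

for name, rp in (("naive", naive), ("adjusted", adjusted)):
    lo, hi, flag = flag_bayes(rp, 0.95)
    print(
        f"{name:>8}: posterior median {rp.median():.3f}, "
        f"95% CI [{lo:.3f}, {hi:.3f}]  ->  flag: {flag}"
    )
print(
    "\nThe naive ratio O/E = 1.30 looks like over-performance; after "
    "dividing out the\nexpected confounding factor exp(0.5) = 1.65 the "
    "center is actually below what its\nresource level predicts, and the "
    "wider adjusted interval reflects uncertainty in\nnu and alpha."
)
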