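"""Robust empirical-null fitting: initialization, likelihood, reductions."""

import math

import numpy as np
import pytest
from scipy import stats

from rppclc import (
    FamilySpec,
    SimStudyConfig,
    en_negloglik,
    fit_normal_mle,
    fit_rppclc,
    gen_estimation_data,
    init_params,
    make_null_intervals,
    sandwich_cov,
    zscores,
)
from rppclc.data_model import stack_providers
from rppclc.estimation import NullIntervals
from rppclc.null_moments import moment_arrays
from conftest import make_provider


@pytest.fixture(scope="module")
def informative_study():
    """A Poisson study at a count scale where all parameters are identified
    (expected counts in the tens to hundreds per cluster)."""
    cfg = SimStudyConfig(seed=12, mu_star=-1.0, outlier_prop=0.1, outlier_c=2.0)
    providers, truth = gen_estimation_data(cfg)
    return cfg, providers, truth


class TestInitParams:
    def test_noiseless_design_recovers_nu_exactly(self, fam_poisson):
        rng = np.random.default_rng(0)
        providers = [
            make_provider(id=f"p{k}", E=50.0 + 10 * k, W=[rng.normal(), rng.normal()])
            for k in range(12)
        ]
        nu_star = np.array([0.3, -0.1])
        _, _, _, nt, W, _ = stack_providers(providers)
        z = np.sqrt(nt)[:, None] * W @ nu_star
        nu0, _, pi00 = init_params(z, providers, fam_poisson)
        assert np.allclose(nu0, nu_star, atol=1e-6)
        assert pi00 == 0.95

    def test_all_zero_covariates_give_zero_nu(self, fam_poisson):
        providers = [make_provider(id=f"p{k}", E=20.0, W=[0.0]) for k in range(8)]
        z = np.linspace(-1, 1, 8)
        nu0, _, _ = init_params(z, providers, fam_poisson)
        assert np.allclose(nu0, 0.0)

    def test_simulated_study_initializer_near_truth(self, fam_poisson):
        cfg = SimStudyConfig(seed=1)
        providers, _ = gen_estimation_data(cfg)
        z = zscores(providers, fam_poisson)
        nu0, _, _ = init_params(z, providers, fam_poisson)
        assert abs(nu0[0] - 0.25) < 0.15

    def test_collinear_design_rejected(self, fam_poisson):
        providers = [
            make_provider(id=f"p{k}", E=30.0, W=[w, 2 * w])
            for k, w in enumerate(np.linspace(-1, 1, 10))
        ]
        with pytest.raises(ValueError, match="rank-deficient"):
            init_params(np.zeros(10), providers, fam_poisson)

    def test_too_few_providers_rejected(self, fam_poisson):
        providers = [make_provider(id="a", E=10.0, W=[0.1])]
        with pytest.raises(ValueError, match="P\\+2"):
            init_params(np.zeros(1), providers, fam_poisson)


class TestNullIntervals:
    def test_standard_case(self):
        iv = make_null_intervals(np.zeros(3), np.zeros(3), np.ones(3), 2.5)
        assert np.allclose(iv.A, -2.5) and np.allclose(iv.B, 2.5)

    def test_infinite_c_puts_everyone_in_the_null_set(self):
        z = np.array([-50.0, 0.0, 80.0])
        iv = make_null_intervals(z, np.zeros(3), np.ones(3), np.inf)
        assert iv.null_mask(z).all()

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError):
            make_null_intervals(np.zeros(2), np.zeros(2), np.ones(2), 0.0)

    def test_outliers_fall_outside_their_intervals(self, fam_poisson,
                                                   informative_study):
        """With informative counts, nearly all true outliers (effect size 2)
        land outside their initialization-based null intervals."""
        _, providers, truth = informative_study
        z = zscores(providers, fam_poisson)
        nu0, s20, _ = init_params(z, providers, fam_poisson)
        _, _, _, nt, W, _ = stack_providers(providers)
        mean0, var0 = moment_arrays(nt, W, nu0, s20, fam_poisson)
        iv = make_null_intervals(z, mean0, var0, 2.5)
        outside = ~iv.null_mask(z)
        assert outside[truth["outlier_idx"]].mean() >= 0.8

    def test_interval_order_invariant(self):
        with pytest.raises(ValueError, match="A_i < B_i"):
            NullIntervals(A=np.array([1.0]), B=np.array([0.0]), c=1.0)


class TestNegLogLik:
    def _setup(self, fam):
        rng = np.random.default_rng(3)
        providers = [
            make_provider(id=f"p{k}", O=rng.poisson(40), E=40.0, W=[rng.normal()])
            for k in range(15)
        ]
        z = zscores(providers, fam)
        return providers, z

    def test_no_truncation_equals_plain_normal_loglik(self, fam_poisson):
        """All providers in the null set with pi0 = 1: the EN likelihood is
        the ordinary normal likelihood at the family moments."""
        providers, z = self._setup(fam_poisson)
        iv = make_null_intervals(z, np.zeros_like(z), np.ones_like(z), np.inf)
        nu, s2 = np.array([0.2]), 0.05
        nll = en_negloglik((nu, s2, 1.0), z, providers, iv, fam_poisson)
        _, _, _, nt, W, _ = stack_providers(providers)
        mean, var = moment_arrays(nt, W, nu, s2, fam_poisson)
        expected = -stats.norm.logpdf(z, mean, np.sqrt(var)).sum()
        assert nll == pytest.approx(expected, rel=1e-12)

    def test_excluded_provider_contributes_exceedance_mass(self, fam_poisson):
        """A provider outside [A, B] contributes -log(1 - pi0 * Q)."""
        p = make_provider(id="x", O=100.0, E=40.0, W=[0.0])
        z = zscores([p], fam_poisson)
        # interval chosen so Q = Phi(b) - Phi(a) is known
        a, b = -1.959963984540054, 1.959963984540054  # Q = 0.95
        iv = NullIntervals(A=np.array([a]), B=np.array([b]), c=2.0)
        nll = en_negloglik((np.zeros(1), 0.0, 1.0), z, [p], iv, fam_poisson)
        assert nll == pytest.approx(-math.log(0.05), rel=1e-6)

    def test_matches_independent_scalar_oracle(self, fam_poisson):
        """Dual-route check: vectorized likelihood equals a per-provider
        recomputation with scipy.stats.norm."""
        providers, z = self._setup(fam_poisson)
        _, _, _, nt, W, _ = stack_providers(providers)
        nu, s2, pi0 = np.array([0.15]), 0.08, 0.9
        mean0, var0 = moment_arrays(nt, W, np.array([0.0]), 0.0, fam_poisson)
        iv = make_null_intervals(z, mean0, var0, 1.5)
        nll = en_negloglik((nu, s2, pi0), z, providers, iv, fam_poisson)
        total = 0.0
        for k, p in enumerate(providers):
            from rppclc import null_moments

            m = null_moments(p, fam_poisson, nu, s2)
            sd = math.sqrt(m.var)
            if iv.A[k] <= z[k] <= iv.B[k]:
                total -= math.log(pi0) + stats.norm.logpdf(z[k], m.mean, sd)
            else:
                q = stats.norm.cdf(iv.B[k], m.mean, sd) - stats.norm.cdf(
                    iv.A[k], m.mean, sd
                )
                total -= math.log(1.0 - pi0 * q)
        assert nll == pytest.approx(total, rel=1e-10)

    def test_domain_violations_rejected(self, fam_poisson):
        providers, z = self._setup(fam_poisson)
        iv = make_null_intervals(z, np.zeros_like(z), np.ones_like(z), 2.5)
        with pytest.raises(ValueError):
            en_negloglik((np.zeros(1), -0.1, 0.9), z, providers, iv, fam_poisson)
        with pytest.raises(ValueError):
            en_negloglik((np.zeros(1), 0.1, 1.2), z, providers, iv, fam_poisson)


class TestFits:
    def test_no_truncation_reduces_to_normal_mle(self, fam_poisson):
        cfg = SimStudyConfig(seed=4, mu_star=-1.0)
        providers, _ = gen_estimation_data(cfg)
        fit_r = fit_rppclc(providers, fam_poisson, c=np.inf, refine=False)
        fit_m = fit_normal_mle(providers, fam_poisson)
        assert fit_r.nu_hat == pytest.approx(fit_m.nu_hat, abs=1e-4)
        assert fit_r.sigma2_alpha_hat == pytest.approx(
            fit_m.sigma2_alpha_hat, abs=1e-4
        )
        assert fit_r.pi0_hat > 0.999

    def test_normal_mle_with_fixed_zero_variance_is_ols(self, fam_normal):
        rng = np.random.default_rng(9)
        n = 40.0
        providers = [
            make_provider(id=f"p{k}", O=rng.normal(10, 2), E=10.0, n_tilde=n,
                          W=[rng.normal()])
            for k in range(30)
        ]
        fit = fit_normal_mle(providers, fam_normal, fix_sigma2=0.0)
        _, _, _, nt, W, _ = stack_providers(providers)
        X = np.sqrt(nt)[:, None] * W
        z = zscores(providers, fam_normal)
        ols = np.linalg.lstsq(X, z, rcond=None)[0]
        assert fit.nu_hat == pytest.approx(ols, abs=1e-8)

    def test_recovery_and_robustness_on_one_dataset(self, fam_poisson,
                                                    informative_study):
        """On contaminated data the robust fit stays near nu = 0.25 while the
        plain MLE is pulled toward the outliers."""
        _, providers, _ = informative_study
        fit_r = fit_rppclc(providers, fam_poisson)
        fit_m = fit_normal_mle(providers, fam_poisson)
        assert abs(fit_r.nu_hat[0] - 0.25) < abs(fit_m.nu_hat[0] - 0.25)
        assert abs(fit_r.nu_hat[0] - 0.25) < 0.1
        assert fit_r.converged

    def test_all_zero_covariates_degenerate_to_variance_only(self, fam_poisson):
        cfg = SimStudyConfig(seed=5, mu_star=-1.0, nu=0.0)
        providers, _ = gen_estimation_data(cfg)
        for p in providers:
            p.W = np.zeros(1)
        fit = fit_rppclc(providers, fam_poisson)
        assert fit.nu_hat[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.sigma2_alpha_hat >= 0.0

    def test_optimum_no_worse_than_initializer(self, fam_poisson,
                                               informative_study):
        _, providers, _ = informative_study
        fit = fit_rppclc(providers, fam_poisson, refine=False)
        z = zscores(providers, fam_poisson)
        nu0, s20, pi00 = init_params(z, providers, fam_poisson)
        nll_init = en_negloglik((nu0, s20, pi00), z, providers, fit.intervals,
                                fam_poisson)
        assert -fit.loglik <= nll_init + 1e-9

    def test_sigma2_recovery_at_informative_scale(self, fam_poisson):
        """Across replicates nu is recovered within Monte-Carlo error and
        sigma2_alpha to within the mild attenuation induced by the c = 2.5
        truncation (the c = inf fit is unbiased but not robust)."""
        nus, s2s = [], []
        for r in range(40):
            cfg = SimStudyConfig(seed=300 + r, mu_star=-1.0)
            providers, _ = gen_estimation_data(cfg)
            fit = fit_rppclc(providers, fam_poisson)
            nus.append(fit.nu_hat[0])
            s2s.append(fit.sigma2_alpha_hat)
        nus, s2s = np.array(nus), np.array(s2s)
        assert abs(nus.mean() - 0.25) < 3 * nus.std(ddof=1) / math.sqrt(len(nus))
        assert abs(s2s.mean() - 0.1) < 0.03


class TestSandwich:
    def test_unit_variance_reduces_to_ols_variance(self, fam_normal):
        # sigma2_alpha = 0 makes Omega the identity: cov = (sum x*^2)^-1
        providers = [
            make_provider(id=f"p{k}", O=1.0, E=1.0, n_tilde=1.0, W=[w])
            for k, w in enumerate([0.5, -1.0, 2.0, 1.5])
        ]
        cov = sandwich_cov(np.zeros(1), 0.0, providers, fam_normal,
                           np.ones(4, dtype=bool))
        xs = np.array([0.5, -1.0, 2.0, 1.5])
        assert cov[0, 0] == pytest.approx(1.0 / np.sum(xs**2), rel=1e-12)

    def test_quadrupling_sizes_halves_the_standard_error(self, fam_normal):
        ws = [0.5, -1.0, 2.0, 1.5, -0.3]
        base = [
            make_provider(id=f"p{k}", O=1.0, E=1.0, n_tilde=10.0, W=[w])
            for k, w in enumerate(ws)
        ]
        big = [
            make_provider(id=f"p{k}", O=1.0, E=1.0, n_tilde=40.0, W=[w])
            for k, w in enumerate(ws)
        ]
        mask = np.ones(5, dtype=bool)
        # Omega fixed: sigma2_alpha = 0 gives Var[Z] = 1 for the Normal family
        c1 = sandwich_cov(np.zeros(1), 0.0, base, fam_normal, mask)
        c2 = sandwich_cov(np.zeros(1), 0.0, big, fam_normal, mask)
        assert c2[0, 0] == pytest.approx(c1[0, 0] / 4.0, rel=1e-12)

    def test_reported_se_tracks_sampling_sd(self, fam_poisson):
        """Calibration: the mean reported SE of nu_hat is within 20% of the
        empirical SD across replicates (no outliers)."""
        nus, ses = [], []
        for r in range(40):
            cfg = SimStudyConfig(seed=500 + r, mu_star=-1.0)
            providers, _ = gen_estimation_data(cfg)
            fit = fit_rppclc(providers, fam_poisson)
            nus.append(fit.nu_hat[0])
            ses.append(math.sqrt(fit.cov_nu[0, 0]))
        sd = np.std(nus, ddof=1)
        assert abs(np.mean(ses) - sd) / sd < 0.2

    def test_small_null_set_rejected(self, fam_poisson):
        providers = [make_provider(id=f"p{k}", E=30.0, W=[0.1 * k]) for k in range(4)]
        with pytest.raises(ValueError, match="null set"):
            sandwich_cov(np.zeros(1), 0.0, providers, fam_poisson,
                         np.zeros(4, dtype=bool))
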