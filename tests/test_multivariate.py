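"""Joint estimators vs closed forms, enumeration and quadrature oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from multirct import (
    MissingnessPlan,
    OutcomeModel,
    apply_missingness,
    em_mm_continuous,
    fit_factorisation,
    fit_lv,
    fit_mm_binary_pair,
    fit_mm_continuous,
    fit_mm_mixed_pair,
    fit_uv,
    simulate,
)
from multirct._bvn import bvn_cdf
from multirct.multivariate import (
    binary_pair_loglik,
    lv_loglik,
    mixed_pair_conditional_logprob,
    mm_continuous_loglik,
)


class TestBvnCdf:
    def test_against_scipy_mvn(self):
        rng = np.random.default_rng(0)
        for rho in (-0.99, -0.6, 0.0, 0.3, 0.8, 0.95, 0.99):
            mvn = stats.multivariate_normal(cov=[[1, rho], [rho, 1]])
            for _ in range(10):
                h, k = rng.normal(size=2) * 1.5
                assert bvn_cdf(h, k, rho) == pytest.approx(mvn.cdf([h, k]), abs=1e-10)


class TestMMContinuous:
    def test_complete_data_equals_per_outcome_ols(self, bivariate_trial):
        mm = fit_mm_continuous(bivariate_trial)
        uv = fit_uv(bivariate_trial)
        for j in range(2):
            assert mm.estimates[j] == pytest.approx(uv[j].estimates[0], abs=1e-8)

    def test_toy_loglik_matches_brute_force(self):
        # 3 participants, distinct missingness patterns, explicit inversion
        data = simulate(OutcomeModel(effects=[0.1, 0.2], rho=0.3), 4, seed=1)
        data.observed[0, 1] = False
        data.outcomes[0, 1] = np.nan
        data.observed[1, 0] = False
        data.outcomes[1, 0] = np.nan
        beta0 = np.array([0.05, -0.1])
        beta1 = np.array([0.3, 0.4])
        Omega = np.array([[1.2, 0.5], [0.5, 0.9]])
        ref = 0.0
        for i in range(4):
            obs = np.flatnonzero(data.observed[i])
            mu = (beta0 + beta1 * data.arm[i])[obs]
            sub = Omega[np.ix_(obs, obs)]
            ref += stats.multivariate_normal(mean=mu, cov=sub).logpdf(
                data.outcomes[i, obs]
            )
        assert mm_continuous_loglik(data, beta0, beta1, Omega) == pytest.approx(
            ref, abs=1e-12
        )

    def test_optimum_dominates_true_parameters(self, mcar_trial):
        res = fit_mm_continuous(mcar_trial)
        assert res.converged
        ll_true = mm_continuous_loglik(
            mcar_trial,
            np.zeros(2),
            np.array([0.35, 0.35]),
            np.array([[1.0, 0.5], [0.5, 1.0]]),
        )
        assert res.nuisance["loglik"] >= ll_true

    def test_gradient_norm_small_at_optimum(self, mcar_trial):
        res = fit_mm_continuous(mcar_trial)
        assert res.nuisance["grad_norm"] < 1e-6

    def test_agrees_with_em_route(self, mcar_trial):
        qn = fit_mm_continuous(mcar_trial)
        _, beta1_em, Omega_em, ll_em = em_mm_continuous(mcar_trial)
        np.testing.assert_allclose(qn.estimates, beta1_em, atol=1e-4)
        assert qn.nuisance["loglik"] == pytest.approx(ll_em, abs=1e-5)

    def test_parameter_recovery_under_mcar(self):
        model = OutcomeModel(effects=[0.35, 0.35], rho=0.8)
        plan = MissingnessPlan("MCAR", [0.3, 0.5])
        est = []
        for s in range(300):
            d = apply_missingness(simulate(model, 260, seed=s), plan, seed=s + 10_000)
            r = fit_mm_continuous(d)
            if r.converged:
                est.append(r.estimates)
        est = np.asarray(est)
        mcse = est.std(axis=0, ddof=1) / np.sqrt(est.shape[0])
        assert (np.abs(est.mean(axis=0) - 0.35) < 3 * mcse).all()

    def test_common_effect_constraint(self, bivariate_trial):
        res = fit_mm_continuous(bivariate_trial, common_effect=True)
        assert res.estimates[0] == res.estimates[1]
        uv = fit_uv(bivariate_trial)
        lo = min(f.estimates[0] for f in uv)
        hi = max(f.estimates[0] for f in uv)
        assert lo - 0.05 < res.estimates[0] < hi + 0.05


@pytest.fixture(scope="module")
def binary_trial():
    shift = stats.norm.ppf(0.65)
    model = OutcomeModel(
        effects=[shift, shift], rho=0.5, outcome_types=("binary", "binary")
    )
    return simulate(model, 340, seed=2)


class TestMMBinaryPair:
    def test_zero_correlation_constraint_equals_independent_probits(self, binary_trial):
        res = fit_mm_binary_pair(binary_trial, constrain_rho_zero=True)
        uv = fit_uv(binary_trial)
        for j in range(2):
            assert res.estimates[j] == pytest.approx(uv[j].estimates[0], abs=1e-6)

    def test_latent_correlation_recovery_large_n(self):
        shift = stats.norm.ppf(0.65)
        model = OutcomeModel(
            effects=[shift, shift], rho=0.8, outcome_types=("binary", "binary")
        )
        d = simulate(model, 10_000, seed=3)
        res = fit_mm_binary_pair(d)
        assert res.converged
        assert res.nuisance["rho"] == pytest.approx(0.8, abs=0.03)

    def test_loglik_equals_multinomial_enumeration(self, binary_trial):
        beta0 = np.array([-0.1, 0.2])
        beta1 = np.array([0.3, 0.25])
        rho = 0.4
        ll = binary_pair_loglik(binary_trial, beta0, beta1, rho)
        ref = 0.0
        for i in range(binary_trial.n):
            a = binary_trial.arm[i]
            e1, e2 = beta0 + beta1 * a
            p11 = bvn_cdf(e1, e2, rho)
            table = {
                (1, 1): p11,
                (1, 0): stats.norm.cdf(e1) - p11,
                (0, 1): stats.norm.cdf(e2) - p11,
            }
            table[(0, 0)] = 1 - sum(table.values())
            y = tuple(int(v) for v in binary_trial.outcomes[i])
            ref += np.log(table[y])
        assert ll == pytest.approx(ref, abs=1e-8)


class TestMMMixedPair:
    def test_zero_correlation_decouples(self, mixed_trial):
        res = fit_mm_mixed_pair(mixed_trial)
        uv = fit_uv(mixed_trial)
        # rho=.5 data: joint and separate fits differ, but at the fitted rho
        # forced to zero they must coincide; simulate an uncorrelated trial
        model = OutcomeModel(
            effects=[0.35, 0.35], rho=0.0, outcome_types=("continuous", "binary")
        )
        d0 = simulate(model, 2000, seed=4)
        joint = fit_mm_mixed_pair(d0)
        sep = fit_uv(d0)
        for j in range(2):
            assert joint.estimates[j] == pytest.approx(sep[j].estimates[0], abs=1e-4)
        assert abs(joint.nuisance["rho"]) < 0.05
        assert res.converged and all(u.converged for u in uv)

    def test_conditional_probability_matches_2d_quadrature(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            b01, b11, b02, b12 = rng.normal(scale=0.5, size=4)
            sigma1 = rng.uniform(0.6, 1.5)
            rho = rng.uniform(-0.8, 0.8)
            x = float(rng.integers(0, 2))
            y1 = rng.normal()
            params = (b01, b11, sigma1, b02, b12, rho)
            got = np.exp(mixed_pair_conditional_logprob(y1, 1.0, x, params))

            # oracle: integrate the joint latent-normal density of (Y1, L2)
            # over the region {L2 > -eta2} at the observed y1
            mu1 = b01 + b11 * x
            eta2 = b02 + b12 * x
            dens = stats.multivariate_normal(
                mean=[mu1, 0.0], cov=[[sigma1**2, rho * sigma1], [rho * sigma1, 1.0]]
            )
            ref = quad(lambda l2: dens.pdf([y1, l2]), -eta2, 10)[0]
            assert got == pytest.approx(ref, abs=1e-6)

    def test_parameter_recovery_large_n(self):
        model = OutcomeModel(
            effects=[0.35, 0.35], rho=0.6, outcome_types=("continuous", "binary")
        )
        d = simulate(model, 10_000, seed=6)
        res = fit_mm_mixed_pair(d)
        assert res.converged
        np.testing.assert_allclose(res.estimates, [0.35, 0.35], atol=0.05)
        assert res.nuisance["rho"] == pytest.approx(0.6, abs=0.05)


class TestLatentVariableModel:
    def test_moment_recovery_two_continuous(self):
        # unit variances, rho=.4, sigma_l2 fixed at .8:
        # implied cross-covariance lambda*sigma_l2 = .4, residuals (.2, .8)
        model = OutcomeModel(effects=[0.35, 0.35], rho=0.4)
        d = simulate(model, 10_000, seed=7)
        res = fit_lv(d)
        assert res.converged
        nu = res.nuisance
        assert nu["loadings"][1] * nu["sigma_l2"] == pytest.approx(0.4, abs=0.05)
        np.testing.assert_allclose(nu["resid_sd"] ** 2, [0.2, 0.8], atol=0.05)
        np.testing.assert_allclose(res.estimates, [0.35, 0.35], atol=0.05)

    def test_binary_rescaling_formula(self):
        from multirct.multivariate import rescale_binary_effect

        assert rescale_binary_effect(1.0, 1.0, 1.0) == pytest.approx(1 / np.sqrt(2))
        assert rescale_binary_effect(0.7, 0.0, 0.8) == pytest.approx(0.7)

    def test_quadrature_refinement_stable(self, mixed_trial):
        beta0 = np.array([0.0, 0.0])
        beta1 = np.array([0.35, 0.35])
        lam = np.array([1.0, 0.8])
        sd = np.array([0.5, 1.0])
        small = mixed_trial
        ll10 = lv_loglik(small, beta0, beta1, lam, sd, 0.8, n_quad=10)
        ll40 = lv_loglik(small, beta0, beta1, lam, sd, 0.8, n_quad=40)
        assert abs(ll10 - ll40) < 1e-4

    def test_adaptive_matches_nonadaptive(self, mixed_trial):
        r1 = fit_lv(mixed_trial, n_quad=10)
        r2 = fit_lv(mixed_trial, n_quad=10, adaptive=True)
        np.testing.assert_allclose(r1.estimates, r2.estimates, atol=1e-3)

    def test_binary_pair_uses_unit_latent_variance(self):
        shift = stats.norm.ppf(0.65)
        model = OutcomeModel(
            effects=[shift, shift], rho=0.4, outcome_types=("binary", "binary")
        )
        d = simulate(model, 1000, seed=8)
        res = fit_lv(d)
        assert res.nuisance["sigma_l2"] == 1.0


class TestFactorisation:
    def test_null_association_tau_near_zero(self):
        model = OutcomeModel(
            effects=[0.35, 0.35], rho=0.0, outcome_types=("continuous", "binary")
        )
        d = simulate(model, 4000, seed=9)
        res = fit_factorisation(d)
        assert abs(res.nuisance["tau"]) < 3 * res.nuisance["tau_se"]

    def test_recovery_from_exact_factorisation_model(self):
        rng = np.random.default_rng(10)
        n = 10_000
        x = np.repeat([0, 1], n // 2)
        mu2 = stats.norm.cdf(0.0 + 0.4 * x)
        y2 = (rng.random(n) < mu2).astype(float)
        y1 = 0.0 + 0.35 * x + 0.5 * (y2 - mu2) + rng.normal(size=n)
        from multirct import TrialData

        data = TrialData(
            arm=x,
            outcomes=np.column_stack([y1, y2]),
            observed=np.ones((n, 2), dtype=bool),
            outcome_types=("continuous", "binary"),
        )
        res = fit_factorisation(data)
        c = res.estimates
        assert c[0] == pytest.approx(0.35, abs=0.05)
        assert c[1] == pytest.approx(0.4, abs=0.05)
        assert res.nuisance["tau"] == pytest.approx(0.5, abs=0.05)

    def test_effect_matches_marginal_ols_when_binary_centred(self):
        # balanced arms: the centred binary regressor is orthogonal to arm in
        # expectation; with within-arm centring the equality is exact
        model = OutcomeModel(
            effects=[0.35, 0.35], rho=0.5, outcome_types=("continuous", "binary")
        )
        d = simulate(model, 2000, seed=11)
        res = fit_factorisation(d)
        # manual OLS with the empirically centred (saturated-probit) residual:
        # the probit step is saturated on arm, so mu2 equals the per-arm mean
        # and the added regressor has exactly zero within-arm mean
        y1 = d.outcomes[:, 0]
        y2 = d.outcomes[:, 1]
        x = d.arm
        marg = fit_uv(d)[0].estimates[0]
        resid = y2.copy()
        for a in (0, 1):
            resid[x == a] -= y2[x == a].mean()
        X = np.column_stack([np.ones(d.n), x, resid])
        beta = np.linalg.solve(X.T @ X, X.T @ y1)
        assert beta[1] == pytest.approx(marg, abs=1e-8)
        assert res.estimates[0] == pytest.approx(beta[1], abs=1e-8)
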