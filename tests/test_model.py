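"""Measurement model: distances, predictions, likelihood, prior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lidm.data import NetworkSpec
from lidm.model import (
    euclidean_distance,
    log_likelihood,
    log_prior,
    predict_response,
)
from lidm.parameters import LidmParameters, PriorSpec
from .conftest import make_sim

vec = st.lists(st.floats(-5, 5), min_size=1, max_size=4)


class TestEuclideanDistance:
    def test_zero_for_equal_vectors(self):
        assert euclidean_distance([1.2, -0.3], [1.2, -0.3]) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance([3, 0], [0, 4]) == pytest.approx(5.0)

    def test_single_dimension_is_absolute_difference(self):
        assert euclidean_distance([2.0], [-1.5]) == pytest.approx(3.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    @given(vec, vec, vec)
    @settings(max_examples=60, deadline=None)
    def test_metric_properties(self, a, b, c):
        k = min(len(a), len(b), len(c))
        a, b, c = a[:k], b[:k], c[:k]
        # elementwise-loop oracle
        oracle = sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
        d_ab = euclidean_distance(a, b)
        assert d_ab == pytest.approx(oracle, abs=1e-12)
        assert d_ab == pytest.approx(euclidean_distance(b, a))
        assert d_ab >= 0
        assert d_ab <= euclidean_distance(a, c) + euclidean_distance(c, b) + 1e-9


def _params(n=3, L=2, T=4, model=1, rho=0.25, seed=0):
    rng = np.random.default_rng(seed)
    return LidmParameters(
        beta0=rng.normal(),
        beta_S=rng.normal(size=T),
        beta_R=np.abs(rng.normal(size=T)) + 0.1,
        sigma=np.exp(rng.normal(0, 0.2, T)),
        theta=rng.normal(size=(n, L)),
        rho_theta=rho,
        beta_D=-rng.uniform(0.05, 0.4, T) if model == 2 else None,
        lam=0.2, sigma_bS=1.1,
    )


class TestPredictResponse:
    def test_null_effects_give_grand_mean(self):
        spec = NetworkSpec.balanced(3, 2, 2)
        p = _params(T=4)
        p.beta_S[:] = 0.0
        p.beta_R[:] = 1e-12
        assert predict_response(1, p, spec, 0, 0, 1) == pytest.approx(
            p.beta0, abs=1e-9)

    def test_model2_with_zero_distance_effect_nests_model1(self):
        spec = NetworkSpec.balanced(4, 2, 2)
        p2 = _params(n=4, T=4, model=2)
        p2.beta_D = np.full(4, -1e-300)
        p1 = _params(n=4, T=4, model=1)
        for item in range(4):
            m2 = predict_response(2, p2, spec, item, 1, 3)
            # same point without the distance term
            p2_as_1 = LidmParameters(
                beta0=p2.beta0, beta_S=p2.beta_S, beta_R=p2.beta_R,
                sigma=p2.sigma, theta=p2.theta, rho_theta=p2.rho_theta)
            m1 = predict_response(1, p2_as_1, spec, item, 1, 3)
            assert m2 == pytest.approx(m1, abs=1e-12)

    def test_worked_arithmetic_on_reported_estimates(self):
        # 15-member trust fit, Model 1: beta0=3.70, item-1 effects
        # (1.24, 0.14), trait scores of members 1 and 2 on the first
        # dimension 0.09 and 0.52: prediction by direct arithmetic.
        spec = NetworkSpec.balanced(15, 2, 3)
        theta = np.zeros((15, 2))
        theta[0, 0], theta[1, 0] = 0.09, 0.52
        p = LidmParameters(beta0=3.70, beta_S=[1.24] + [0.0] * 5,
                           beta_R=[0.14] + [1e-9] * 5, sigma=np.ones(6),
                           theta=theta, rho_theta=0.41)
        assert predict_response(1, p, spec, 0, 0, 1) == pytest.approx(3.8844)

    def test_self_rating_rejected(self):
        spec = NetworkSpec.balanced(3, 2, 2)
        with pytest.raises(ValueError):
            predict_response(1, _params(), spec, 0, 1, 1)

    def test_model2_requires_distance_effects(self):
        spec = NetworkSpec.balanced(3, 2, 2)
        with pytest.raises(ValueError):
            predict_response(2, _params(model=1), spec, 0, 0, 1)


class TestLogLikelihood:
    def test_single_observation_at_its_mean(self):
        # one response exactly at the predicted mean with unit residual SD
        _, params, table = make_sim(n=3, seed=4, items_per_subscale=1)
        frame = table.to_dataframe()
        from lidm.data import DyadicResponseTable
        p = _params(n=3, T=2)
        p.sigma[:] = 1.0
        sub = DyadicResponseTable(frame)
        s, r, i, y = sub.arrays()
        from lidm.model import _predicted_means
        mu = _predicted_means(1, p, sub.spec, s, r, i)
        frame = frame.copy()
        frame["response"] = mu
        exact = DyadicResponseTable(frame)
        ll = log_likelihood(1, p, exact)
        assert ll == pytest.approx(len(frame) * (-0.5 * np.log(2 * np.pi)))

    def test_per_observation_density_oracle(self):
        _, truth, table = make_sim(n=4, seed=6, items_per_subscale=2)
        p = _params(n=4, T=4, seed=3)
        s, r, i, y = table.arrays()
        from lidm.model import _predicted_means
        mu = _predicted_means(1, p, table.spec, s, r, i)
        oracle = sum(stats.norm.logpdf(yk, mk, p.sigma[ik])
                     for yk, mk, ik in zip(y, mu, i))
        assert log_likelihood(1, p, table) == pytest.approx(oracle)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_model_nesting_identity(self, seed):
        _, _, table = make_sim(n=4, seed=seed)
        p1 = _params(n=4, T=8, seed=seed)
        p2 = LidmParameters(
            beta0=p1.beta0, beta_S=p1.beta_S, beta_R=p1.beta_R,
            sigma=p1.sigma, theta=p1.theta, rho_theta=p1.rho_theta,
            beta_D=np.full(8, -1e-300))
        assert abs(log_likelihood(2, p2, table)
                   - log_likelihood(1, p1, table)) < 1e-10

    def test_nonpositive_sigma_rejected(self):
        _, _, table = make_sim(n=4, seed=0)
        p = _params(n=4, T=8)
        p.sigma[0] = -1.0
        with pytest.raises(ValueError):
            log_likelihood(1, p, table)


class TestLogPrior:
    def test_negative_receiver_effect_outside_support(self):
        p = _params()
        p.beta_R[0] = -0.2
        assert log_prior(1, p, PriorSpec()) == -np.inf

    def test_positive_distance_effect_outside_support(self):
        p = _params(model=2)
        p.beta_D[1] = +0.1
        assert log_prior(2, p, PriorSpec()) == -np.inf
        assert not np.isnan(log_prior(2, p, PriorSpec()))

    def test_component_wise_oracle(self):
        pr = PriorSpec()
        p = _params(n=3, L=2, T=4, model=2, seed=11)
        got = log_prior(2, p, pr)
        s2c = p.sigma_bS ** 2 - p.lam ** 2
        cov = np.array([[1, p.rho_theta], [p.rho_theta, 1]])
        tau = 1.0 / p.sigma ** 2
        expected = (
            stats.norm.logpdf(p.beta0, 0, np.sqrt(10))
            + np.sum(stats.halfnorm.logpdf(p.beta_R, scale=1.0))
            + np.sum(stats.norm.logpdf(p.beta_S, p.lam * p.beta_R,
                                       np.sqrt(s2c)))
            + np.sum(stats.lognorm.logpdf(-p.beta_D, np.sqrt(10)))
            + sum(stats.multivariate_normal.logpdf(row, np.zeros(2), cov)
                  for row in p.theta)
            + np.sum(stats.gamma.logpdf(tau, 0.01, scale=100.0))
            + np.sum(np.log(2.0 / p.sigma ** 3))
            + stats.norm.logpdf(p.lam, 0, np.sqrt(1000))
            - np.log(999.0)
        )
        assert got == pytest.approx(expected)

    def test_precision_convention_flag(self):
        p = _params()
        loose = log_prior(1, p, PriorSpec())
        tight = log_prior(1, p, PriorSpec(scales_are_precisions=True))
        assert loose != tight  # N(0, var 10) vs N(0, var 1/10) on beta0


class TestMeasurementEquationOracle:
    def test_ols_recovers_item_effects_at_vanishing_noise(self):
        """With traits and distances observed, per-item least squares on
        (theta_S, theta_R, E) recovers the generating effects."""
        import statsmodels.api as sm

        cfg, truth, table = make_sim(n=12, model=2, seed=8,
                                     residual_sd=1e-6)
        s, r, i, y = table.arrays()
        sub = np.asarray(table.spec.item_to_subscale)[i] - 1
        E = np.sqrt(np.sum((truth.theta[s] - truth.theta[r]) ** 2, axis=1))
        for item in range(table.spec.n_items):
            m = i == item
            X = np.column_stack([truth.theta[s[m], sub[m]],
                                 truth.theta[r[m], sub[m]], E[m]])
            fit = sm.OLS(y[m] - truth.beta0, X).fit()
            np.testing.assert_allclose(
                fit.params,
                [truth.beta_S[item], truth.beta_R[item], truth.beta_D[item]],
                atol=1e-4)
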