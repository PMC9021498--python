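"""MCMC estimation: correctness, support constraints, determinism."""

import numpy as np
import pytest
from scipy import stats

from lidm.model import FitConfig, LatentInterdependenceModel
from .conftest import make_sim


class TestFitConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(iterations=100, burnin=100)
        with pytest.raises(ValueError):
            FitConfig(thin=0)

    def test_reference_settings_shape(self):
        cfg = FitConfig.reference_settings()
        assert cfg.n_chains == 2
        assert cfg.iterations == 100_000
        assert cfg.burnin == 50_000
        assert cfg.thin == 2
        assert cfg.kept_per_chain == 25_000


class TestPosteriorCorrectness:
    def test_grand_mean_recovered_within_three_posterior_sd(self):
        _, truth, table = make_sim(n=30, model=1, seed=77)
        res = LatentInterdependenceModel(table, model=1).fit(
            FitConfig.reduced(seed=5))
        draws = res.get("beta0")
        assert abs(draws.mean() - truth.beta0) < 3 * draws.std() + 1e-9

    def test_prior_only_run_recovers_prior(self):
        # with the likelihood switched off the trait-correlation draws
        # must reproduce their U(0,1) prior
        _, _, table = make_sim(n=4, seed=12)
        res = LatentInterdependenceModel(table, model=1).fit(
            FitConfig(n_chains=2, iterations=4000, burnin=500, seed=2,
                      prior_only=True))
        rho = res.get("rho_theta").ravel()
        assert rho.mean() == pytest.approx(0.5, abs=0.05)
        beta0 = res.get("beta0").ravel()
        assert beta0.std() == pytest.approx(np.sqrt(10.0), rel=0.15)

    def test_support_constraints_every_retained_draw(self, small_fit_m2):
        _, res = small_fit_m2
        T = res.model.spec.n_items
        for i in range(1, T + 1):
            assert np.all(res.get(f"beta_R[{i}]") > 0)
            assert np.all(res.get(f"beta_D[{i}]") < 0)
            assert np.all(res.get(f"sigma[{i}]") > 0)
        rho = res.get("rho_theta")
        assert np.all((rho > 0) & (rho < 1))

    def test_conjugate_gamma_reduction(self):
        """With every block but the residual precisions frozen at truth,
        each tau_i must be drawn from its closed-form gamma conditional
        Gamma(a + N_i/2, b + SSE_i/2)."""
        from lidm.model import _predicted_means

        _, truth, table = make_sim(n=6, model=1, seed=21)
        mask = np.zeros(8, dtype=np.uint8)
        mask[4] = 1  # tau only
        res = LatentInterdependenceModel(table, model=1).fit(
            FitConfig(n_chains=2, iterations=2500, burnin=100, seed=31),
            update_mask=mask, start=truth)
        s, r, i, y = table.arrays()
        mu = _predicted_means(1, truth, table.spec, s, r, i)
        for item in [0, 3, 7]:
            m = i == item
            sse = float(np.sum((y[m] - mu[m]) ** 2))
            shape = 0.01 + 0.5 * m.sum()
            rate = 0.01 + 0.5 * sse
            tau_draws = 1.0 / res.get(f"sigma[{item + 1}]").ravel() ** 2
            p = stats.kstest(tau_draws,
                             stats.gamma(shape, scale=1 / rate).cdf).pvalue
            assert p > 1e-3

    def test_model2_nests_model1_in_posterior_means(self):
        # loose sanity: both models' beta0 EAPs agree on model-1 data
        _, truth, table = make_sim(n=8, model=1, seed=55)
        r1 = LatentInterdependenceModel(table, model=1).fit(
            FitConfig.reduced(seed=1))
        r2 = LatentInterdependenceModel(table, model=2).fit(
            FitConfig.reduced(seed=2))
        assert abs(r1.eap("beta0") - r2.eap("beta0")) < 0.5


class TestReproducibilityAndShape:
    def test_seed_determinism(self):
        _, _, table = make_sim(n=5, seed=3)
        m = LatentInterdependenceModel(table, model=1)
        cfg = FitConfig(n_chains=2, iterations=300, burnin=100, seed=17)
        a = m.fit(cfg)
        b = m.fit(cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_retained_draw_count_and_thinning(self):
        _, _, table = make_sim(n=4, seed=3)
        cfg = FitConfig(n_chains=3, iterations=402, burnin=100, thin=3,
                        seed=1)
        res = LatentInterdependenceModel(table, model=1).fit(cfg)
        assert res.draws.shape[0] == 3
        assert res.draws.shape[1] == cfg.kept_per_chain == 101

    def test_summary_table_layout(self, small_fit_m1):
        _, res = small_fit_m1
        summ = res.summary()
        assert list(summ.columns) == ["mean", "sd", "median", "rhat", "ess"]
        assert "beta0" in summ.index
        assert "theta[8,2]" in summ.index
        assert (summ["ess"].dropna()
                <= res.draws.shape[0] * res.draws.shape[1] + 1e-9).all()
        assert (summ["rhat"].dropna() >= 1.0).all()

    def test_eap_params_round_trip(self, small_fit_m1, tmp_path):
        _, res = small_fit_m1
        p = res.params
        path = tmp_path / "eap.yaml"
        p.save(path)
        from lidm.parameters import LidmParameters
        back = LidmParameters.load(path)
        np.testing.assert_allclose(back.theta, p.theta)
        np.testing.assert_allclose(back.beta_R, p.beta_R)

    def test_save_draws_columnar_text(self, small_fit_m1, tmp_path):
        import pandas as pd
        _, res = small_fit_m1
        path = tmp_path / "draws.csv"
        res.save_draws(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == res.names
        assert len(frame) == res.draws.shape[0] * res.draws.shape[1]

    def test_too_small_network_rejected(self, trust_table):
        import pandas as pd
        frame = trust_table.to_dataframe()
        frame = frame[frame.sender.isin([1, 2]) & frame.receiver.isin([1, 2])]
        from lidm.data import DyadicResponseTable
        two = DyadicResponseTable(frame)
        with pytest.raises(ValueError):
            LatentInterdependenceModel(two, model=1)

    def test_trust_example_fit_smoke(self, trust_table):
        res = LatentInterdependenceModel(trust_table, model=1).fit(
            FitConfig.reduced(seed=4))
        assert np.isfinite(res.eap("beta0"))
        # 7-point ratings centered well above zero
        assert 2.0 < res.eap("beta0") < 5.0
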