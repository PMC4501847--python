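"""Generative-model, likelihood and inference tests for the
isoform-preference models."""

import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from batseq.batbayes import (BatBayesParams, McmcConfig, ObservedIsoforms,
                             compute_dic, fit_model, observed_loglik,
                             simulate_dataset)
from batseq.synth import simulate_study_counts


def brute_force_loglik(k1, k2, mu, cv, beta, p, tol=1e-12):
    """Exhaustive sum over the latent molecule count Q and partitions.

    P(k1, k2) = sum_Q NB(Q; mu, cv) * Multinomial(k1, k2, Q-K;
    p*beta, (1-p)*beta, 1-beta).  Truncation extends until the NB tail is
    below ``tol``.
    """
    from scipy.special import gammaln

    K = k1 + k2
    r = mu / (cv ** 2 * mu - 1.0)
    nb_p = r / (r + mu)
    total = 0.0
    Q = K
    while True:
        nbq = stats.nbinom.pmf(Q, r, nb_p)
        logmult = (gammaln(Q + 1) - gammaln(k1 + 1) - gammaln(k2 + 1)
                   - gammaln(Q - K + 1)
                   + k1 * np.log(p * beta) + k2 * np.log((1 - p) * beta)
                   + (Q - K) * np.log1p(-beta))
        increment = nbq * np.exp(logmult)
        total += increment
        # terms decay geometrically once Q >> K; stop when the running
        # term is negligible relative to the accumulated mass
        if Q > K + 20 and increment < total * tol:
            break
        if Q > K + 100_000:
            raise RuntimeError("oracle failed to converge")
        Q += 1
    return np.log(total)


class TestSimulateDataset:
    def test_zero_sigma_means_identical_preferences(self):
        params = BatBayesParams(mu=50.0, cv=0.6, eta=0.4, beta=0.5,
                                sigma=0.0)
        _, truth = simulate_dataset(params, 5, 200, seed=0)
        assert np.all(truth["p"] == truth["p"][:, :1])

    def test_degenerate_channel_pure_isoform1(self):
        params = BatBayesParams(mu=30.0, cv=0.7, eta=40.0, beta=1.0,
                                sigma=0.0)
        data, truth = simulate_dataset(params, 3, 50, seed=1)
        assert np.array_equal(data.k1, truth["Q"])
        assert np.all(data.k2 == 0)

    def test_moments_match_negative_binomial(self):
        mu, cv = 50.0, 0.6
        params = BatBayesParams(mu=mu, cv=cv, eta=0.0, beta=1.0, sigma=0.0)
        _, truth = simulate_dataset(params, 1, 10_000, seed=2)
        Q = truth["Q"][0]
        se_mean = cv * mu / np.sqrt(len(Q))
        assert abs(Q.mean() - mu) < 3 * se_mean
        # delta-method SE of the sample CV
        cv_hat = Q.std() / Q.mean()
        assert abs(cv_hat - cv) < 3 * 0.01 * cv * np.sqrt(10_000) / len(Q) \
            + 0.03

    def test_representability_constraint_enforced(self):
        with pytest.raises(ValueError, match="negative-binomial|cv_g"):
            BatBayesParams(mu=2.0, cv=0.1, eta=0.0, beta=0.5)


class TestObservedLoglik:
    def test_factorises_at_full_capture(self):
        """With beta = 1, P(k1=1, k2=0) = P(K=1) * p."""
        mu, cv, p = 1.0, 1.5, 0.5
        r = mu / (cv ** 2 * mu - 1)
        data = ObservedIsoforms(np.array([[1]]), np.array([[0]]))
        params = BatBayesParams(mu=mu, cv=cv, eta=0.0, beta=1.0,
                                p=np.array([[p]]))
        want = np.log(stats.nbinom.pmf(1, r, r / (r + mu)) * p)
        assert observed_loglik(data, params) == pytest.approx(want)

    def test_vanishing_capture_all_zero_data(self):
        data = ObservedIsoforms(np.zeros((2, 3)), np.zeros((2, 3)))
        params = BatBayesParams(mu=50.0, cv=0.6, eta=0.0, beta=1e-12,
                                p=np.full((2, 3), 0.5))
        assert observed_loglik(data, params) == pytest.approx(0.0, abs=1e-6)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            ObservedIsoforms(np.array([[0.5]]), np.array([[0]]))

    def test_matches_exhaustive_latent_sum(self):
        """Collapsed likelihood equals the brute-force sum over the latent
        molecule count on random small instances."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            mu = rng.uniform(0.5, 5.0)
            cv = rng.uniform(np.sqrt(1.2 / mu), 2.0)
            beta = rng.uniform(0.05, 0.95)
            p = rng.uniform(0.05, 0.95)
            k1 = int(rng.integers(0, 4))
            k2 = int(rng.integers(0, 4))
            data = ObservedIsoforms(np.array([[k1]]), np.array([[k2]]))
            params = BatBayesParams(mu=mu, cv=cv, eta=0.0, beta=beta,
                                    p=np.array([[p]]))
            want = brute_force_loglik(k1, k2, mu, cv, beta, p)
            assert observed_loglik(data, params) == pytest.approx(
                want, abs=1e-8)


@pytest.fixture(scope="module")
def small_fit():
    """One variable-preference fit on study-condition data, shared by the
    inference tests below."""
    data, beta, truth = simulate_study_counts(n_genes=60, n_cells=30,
                                              sigma=0.5, seed=202)
    cfg = McmcConfig(chains=2, iters=1500, warmup=750, seed=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_model(data, beta, "variable_pref", cfg)
    return data, beta, truth, fit


class TestFitModel:
    def test_recovers_gene_means_and_preferences(self, small_fit):
        """Posterior intervals for mu_g and eta_g cover the generating
        values at roughly nominal rates."""
        data, beta, truth, fit = small_fit
        mu_draws = fit.draws["mu"].reshape(-1, 60)
        lo, hi = np.percentile(mu_draws, [2.5, 97.5], axis=0)
        cover_mu = np.mean((truth["mu"] >= lo) & (truth["mu"] <= hi))
        eta_draws = fit.draws["eta"].reshape(-1, 60)
        lo, hi = np.percentile(eta_draws, [2.5, 97.5], axis=0)
        cover_eta = np.mean((truth["eta"] >= lo) & (truth["eta"] <= hi))
        assert cover_mu > 0.85
        assert cover_eta > 0.85

    def test_posterior_predictive_total_conservation(self, small_fit):
        """Simulating from posterior means reproduces per-gene mean totals
        for nearly all genes."""
        data, beta, truth, fit = small_fit
        params = BatBayesParams(
            mu=fit.posterior_mean("mu"), cv=fit.posterior_mean("cv"),
            eta=fit.posterior_mean("eta"), beta=beta, p=fit.p_mean)
        reps = []
        for s in range(20):
            rep, _ = simulate_dataset(params, *data.shape, seed=900 + s)
            reps.append(rep.K.mean(axis=1))
        reps = np.array(reps)
        obs = data.K.mean(axis=1)
        z = (obs - reps.mean(axis=0)) / (reps.std(axis=0)
                                         * np.sqrt(1 + 1 / 20))
        assert np.mean(np.abs(z) < 3) >= 0.9

    def test_variable_model_nests_shared(self):
        """With sigma pinned near zero the variable-preference model
        reproduces the shared-preference posteriors."""
        data, beta, _ = simulate_study_counts(n_genes=30, n_cells=25,
                                              sigma=0.0, seed=33)
        cfg = McmcConfig(chains=2, iters=1200, warmup=600, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_nested = fit_model(data, beta, "variable_pref", cfg,
                                 fix_sigma=0.02)
            f_shared = fit_model(data, beta, "shared_pref", cfg)
        eta_n = f_nested.posterior_mean("eta")
        eta_s = f_shared.posterior_mean("eta")
        sd_s = f_shared.draws["eta"].reshape(-1, 30).std(axis=0)
        assert np.mean(np.abs(eta_n - eta_s) < 3 * sd_s + 0.05) > 0.9

    def test_no_information_prior_dominated(self):
        data = ObservedIsoforms(np.array([[0, 0]]), np.array([[1, 1]]))
        cfg = McmcConfig(chains=2, iters=800, warmup=400, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(data, np.array([0.5, 0.5]), "variable_pref", cfg)
        # two cells, one molecule each: p posterior stays diffuse,
        # pulled below 1/2 but far from 0
        assert 0.05 < fit.p_mean.mean() < 0.5

    def test_all_zero_gene_dropped_with_warning(self):
        k1 = np.array([[3, 2], [0, 0]])
        k2 = np.array([[1, 1], [0, 0]])
        data = ObservedIsoforms(k1, k2)
        cfg = McmcConfig(chains=1, iters=200, warmup=100, seed=0)
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_model(data, np.array([0.5, 0.5]), "variable_pref", cfg)
        assert fit.p_mean.shape[0] == 1

    def test_too_few_cells_rejected(self):
        data = ObservedIsoforms(np.array([[1]]), np.array([[1]]))
        with pytest.raises(ValueError):
            fit_model(data, np.array([0.5]), "variable_pref")


class TestComputeDic:
    def test_degenerate_posterior_has_zero_pd(self, small_fit):
        """A trace of identical draws gives pD = 0 and DIC = D(theta)."""
        data, beta, truth, fit = small_fit
        frozen = type(fit)(
            model=fit.model,
            draws={k: np.repeat(v[:, :1], 20, axis=1)
                   for k, v in fit.draws.items()},
            p_mean=fit.p_mean, p_sd=fit.p_sd,
            deviance=np.repeat(fit.deviance[:, :1], 20, axis=1),
            beta=fit.beta)
        nz = data.K.sum(axis=1) > 0
        sub = ObservedIsoforms(data.k1[nz], data.k2[nz])
        # make the single retained draw self-consistent with p_mean
        params = BatBayesParams(
            mu=frozen.posterior_mean("mu"), cv=frozen.posterior_mean("cv"),
            eta=frozen.posterior_mean("eta"), beta=beta, p=fit.p_mean)
        dev = -2.0 * observed_loglik(sub, params)
        frozen.deviance[:] = dev
        dic = compute_dic(frozen, sub)
        assert dic.pd == pytest.approx(0.0, abs=1e-6)
        assert dic.dic == pytest.approx(dev, rel=1e-9)

    def test_requires_enough_draws(self, small_fit):
        data, beta, truth, fit = small_fit
        short = type(fit)(
            model=fit.model,
            draws={k: v[:, :2] for k, v in fit.draws.items()},
            p_mean=fit.p_mean, p_sd=fit.p_sd,
            deviance=fit.deviance[:1, :2], beta=fit.beta)
        with pytest.raises(ValueError, match="10"):
            compute_dic(short, data)

    def test_pd_positive_on_real_fit(self, small_fit):
        data, beta, truth, fit = small_fit
        dic = compute_dic(fit, data)
        assert dic.pd > 0
        assert dic.dic == pytest.approx(dic.dbar + dic.pd)


class TestSummaries:
    def test_summary_table_contents(self, small_fit):
        _, _, _, fit = small_fit
        df = fit.summary(("sigma", "tau"))
        assert set(df["parameter"]) == {"sigma", "tau"}
        assert (df["q2.5"] <= df["q97.5"]).all()
        assert np.isfinite(df["rhat"]).all()
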