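import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multinomial, norm

from bayesce.inference import (LikelihoodContext, PosteriorSample, PriorSpec,
                               TransitionData, default_priors, log_likelihood,
                               log_prior, posterior_mean_linear_predictors,
                               sample_posterior)
from bayesce.model_spec import (build_model_config, build_parameter_index,
                                transition_probabilities, two_state_config)
from conftest import make_single_row


class TestTransitionData:
    def test_row_totals(self, m1_cohort):
        assert np.all(m1_cohort.totals == m1_cohort.counts.sum(axis=1))

    def test_counts_on_forbidden_transition_rejected(self, m1_config):
        # state 2 -> state 3 is not permitted
        data = make_single_row(m1_config, 2, {2: 10, 3: 1}, aad=1)
        with pytest.raises(ValueError, match="non-permitted .* rows \\[0\\]"):
            data.validate(m1_config)

    def test_missing_covariate_column_rejected(self, m1_config):
        rows = pd.DataFrame([{"patient": 1, "year": 0, "from_state": 1,
                              "age": 63.0, "aad": 1}])
        data = TransitionData(rows, np.zeros((1, 8)))
        with pytest.raises(ValueError, match="missing covariate"):
            data.validate(m1_config)

    def test_negative_counts_rejected(self):
        rows = pd.DataFrame([{"patient": 1, "year": 0, "from_state": 1,
                              "age": 63.0}])
        with pytest.raises(ValueError, match="negative"):
            TransitionData(rows, np.full((1, 8), -1.0))

    def test_csv_round_trip(self, m1_cohort, tmp_path):
        path = tmp_path / "data.csv"
        m1_cohort.to_csv(path)
        back = TransitionData.from_csv(path, 8)
        assert back.n_rows == m1_cohort.n_rows
        # same multiset of (patient, year, from_state) keys and counts
        key = ["patient", "year", "from_state"]
        a = m1_cohort.rows[key].sort_values(key).reset_index(drop=True)
        b = back.rows[key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
        order_a = np.lexsort(m1_cohort.rows[key].to_numpy().T)
        order_b = np.lexsort(back.rows[key].to_numpy().T)
        np.testing.assert_allclose(m1_cohort.counts[order_a], back.counts[order_b])


class TestLogLikelihood:
    def test_empty_data_zero(self, m1_config):
        data = TransitionData.empty(m1_config)
        assert log_likelihood(np.zeros(59), data, m1_config) == 0.0

    def test_single_transition_uniform(self, m1_config):
        data = make_single_row(m1_config, 1, {2: 1}, aad=1, lvef=1, country=1)
        ll = log_likelihood(np.zeros(59), data, m1_config)
        assert ll == pytest.approx(np.log(1 / 8), abs=1e-12)

    def test_year_of_days_vs_scipy(self, m1_config):
        data = make_single_row(m1_config, 1, {1: 363, 2: 1, 3: 1}, aad=1)
        ll = log_likelihood(np.zeros(59), data, m1_config)
        counts = np.array([363, 1, 1, 0, 0, 0, 0, 0])
        oracle = multinomial.logpmf(counts, 365, np.full(8, 1 / 8))
        assert ll == pytest.approx(oracle, abs=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_against_multinomial_pmf_oracle(self, seed):
        """Random small datasets: total log-lik equals the sum of per-row
        scipy multinomial log-pmfs at the model's own probabilities."""
        cfg = build_model_config("M1")
        index = build_parameter_index(cfg)
        rng = np.random.default_rng(seed)
        theta = rng.normal(0, 0.8, index.n_free)
        n_rows = rng.integers(1, 6)
        recs, counts = [], []
        for i in range(n_rows):
            r = int(rng.integers(1, 8))
            raw = {"aad": float(rng.integers(2)), "sex": float(rng.integers(2)),
                   "lvef": float(rng.integers(2)), "country": float(rng.integers(2))}
            age = float(rng.uniform(45, 85))
            x = cfg.covariate_vector(raw, age)
            p = transition_probabilities(index, theta, x, r)
            N = int(rng.integers(1, 200))
            cnt = rng.multinomial(N, p)
            recs.append({"patient": i, "year": 0, "from_state": r, "age": age, **raw})
            counts.append(cnt)
        data = TransitionData(pd.DataFrame(recs), np.array(counts, dtype=float))
        ll = log_likelihood(theta, data, cfg)
        oracle = 0.0
        for i in range(n_rows):
            r = int(data.rows["from_state"].iloc[i])
            raw = {c: float(data.rows[c].iloc[i]) for c in cfg.raw_covariate_names}
            x = cfg.covariate_vector(raw, float(data.rows["age"].iloc[i]))
            p = transition_probabilities(index, theta, x, r)
            keep = p > 0
            oracle += multinomial.logpmf(
                counts[i][keep], counts[i].sum(), p[keep])
        assert ll == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    def test_tying_invariance_under_source_permutation(self, m1_config):
        """Swapping which source state a death is observed from (with the
        same occupancy) leaves the likelihood unchanged: death-row
        parameters are shared."""
        theta = np.random.default_rng(5).normal(0, 0.5, 59)
        d1 = make_single_row(m1_config, 2, {2: 99, 8: 1}, aad=1)
        d2 = make_single_row(m1_config, 3, {3: 99, 8: 1}, aad=1)
        # stay intercepts differ between rows 2/3, so equalize them
        index = build_parameter_index(m1_config)
        theta[index.position[(3, 3, 0)]] = theta[index.position[(2, 2, 0)]]
        theta[index.position[(3, 3, 4)]] = theta[index.position[(2, 2, 4)]]
        ll1 = log_likelihood(theta, d1, m1_config)
        ll2 = log_likelihood(theta, d2, m1_config)
        assert ll1 == pytest.approx(ll2, rel=1e-12)


class TestLogPrior:
    def test_density_at_mode(self):
        priors = PriorSpec(np.zeros(3), np.array([10.0, 10.0, 0.16]))
        expected = np.sum(np.log(1 / (priors.sd * np.sqrt(2 * np.pi))))
        assert log_prior(priors.mean, priors) == pytest.approx(expected)

    def test_hand_evaluated_normal(self):
        priors = PriorSpec(np.array([0.0]), np.array([10.0]))
        expected = norm.logpdf(1.0) - np.log(10.0)  # z = 1 minus log scale
        assert log_prior(np.array([10.0]), priors) == pytest.approx(expected)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(size=5)
        mean = rng.normal(size=5)
        sd = np.abs(rng.normal(size=5)) + 0.1
        shift = 3.7
        a = log_prior(theta, PriorSpec(mean, sd))
        b = log_prior(theta + shift, PriorSpec(mean + shift, sd))
        assert a == pytest.approx(b)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(np.zeros(2), np.array([1.0, 0.0]))


class TestSampler:
    def test_reproducible(self, two_state, two_state_data):
        a = sample_posterior(two_state_data, two_state, n_iter=600,
                             n_burnin=100, seed=3)
        b = sample_posterior(two_state_data, two_state, n_iter=600,
                             n_burnin=100, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_invalid_iterations(self, two_state, two_state_data):
        with pytest.raises(ValueError):
            sample_posterior(two_state_data, two_state, n_iter=100, n_burnin=100)

    def test_deviance_matches_likelihood(self, two_state, two_state_data):
        s = sample_posterior(two_state_data, two_state, n_iter=600,
                             n_burnin=100, seed=3)
        i = 37
        ll = log_likelihood(s.draws[i], two_state_data, two_state)
        assert s.deviance[i] == pytest.approx(-2 * ll, rel=1e-9)

    def test_conjugate_grid_oracle(self, two_state, two_state_data):
        """MCMC quantiles match dense numerical integration of the
        1-parameter posterior within Monte-Carlo tolerance."""
        s = sample_posterior(two_state_data, two_state, n_iter=9000,
                             n_burnin=1000, seed=7)
        grid = np.linspace(-14, 2, 6001)
        ctx = LikelihoodContext(two_state_data, two_state)
        logpost = np.array(
            [log_likelihood(np.array([m]), two_state_data, two_state, ctx)
             for m in grid]) - 0.5 * (grid / 10.0) ** 2
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean = (grid * w).sum()
        sd = np.sqrt((grid ** 2 * w).sum() - mean ** 2)
        cdf = np.cumsum(w)
        draws = s.draws[:, 0]
        mc_se = sd / np.sqrt(200)  # conservative effective sample size
        assert draws.mean() == pytest.approx(mean, abs=4 * mc_se)
        assert draws.std() == pytest.approx(sd, rel=0.15)
        for q in (0.25, 0.5, 0.75):
            grid_q = grid[np.searchsorted(cdf, q)]
            assert np.quantile(draws, q) == pytest.approx(grid_q, abs=5 * mc_se)

    def test_prior_only_run_matches_prior(self, m1_config):
        data = TransitionData.empty(m1_config)
        s = sample_posterior(data, m1_config, n_iter=4000, n_burnin=1000, seed=4)
        index = build_parameter_index(m1_config)
        priors = default_priors(index)
        se = priors.sd / np.sqrt(150)
        assert np.all(np.abs(s.mean() - priors.mean) < 4 * se)

    def test_informative_death_prior_recovered(self, m1_config):
        data = TransitionData.empty(m1_config)
        s = sample_posterior(data, m1_config, n_iter=4000, n_burnin=1000, seed=5)
        index = build_parameter_index(m1_config)
        j = index.names.index("beta_D_aad")
        assert s.draws[:, j].mean() == pytest.approx(0.414, abs=0.04)
        assert s.draws[:, j].std() == pytest.approx(0.16, rel=0.2)

    def test_seeds_agree_gelman_rubin(self, two_state, two_state_data):
        chains = [sample_posterior(two_state_data, two_state, n_iter=4000,
                                   n_burnin=1000, seed=s).draws[:, 0]
                  for s in (1, 2, 3)]
        draws = np.array(chains)
        m, n = draws.shape
        W = draws.var(axis=1, ddof=1).mean()
        B = n * draws.mean(axis=1).var(ddof=1)
        rhat = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat < 1.1

    def test_acceptance_near_target(self, m1_sample):
        assert 0.25 < np.mean(m1_sample.acceptance) < 0.6


class TestPosteriorSummaries:
    def test_single_draw_predictors(self, m1_config, m1_cohort, m1_sample):
        one = PosteriorSample(m1_sample.draws[:1], m1_sample.deviance[:1],
                              m1_sample.names, 0, 1, 0)
        ctx = LikelihoodContext(m1_cohort, m1_config)
        eta = posterior_mean_linear_predictors(one, m1_cohort, m1_config, ctx)
        np.testing.assert_allclose(eta, ctx.eta_matrix(m1_sample.draws[0]))

    def test_two_draw_average(self, m1_config, m1_cohort, m1_sample):
        two = PosteriorSample(m1_sample.draws[:2], m1_sample.deviance[:2],
                              m1_sample.names, 0, 2, 0)
        ctx = LikelihoodContext(m1_cohort, m1_config)
        eta = posterior_mean_linear_predictors(two, m1_cohort, m1_config, ctx)
        a = ctx.eta_matrix(m1_sample.draws[0])
        b = ctx.eta_matrix(m1_sample.draws[1])
        np.testing.assert_allclose(eta, (a + b) / 2)

    def test_linearity_equality(self, m1_config, m1_cohort, m1_sample):
        """Average of per-draw predictors equals predictors at the
        posterior-mean theta (they coincide by linearity)."""
        ctx = LikelihoodContext(m1_cohort, m1_config)
        eta = posterior_mean_linear_predictors(m1_sample, m1_cohort,
                                               m1_config, ctx)
        at_mean = ctx.eta_matrix(m1_sample.mean())
        np.testing.assert_allclose(eta, at_mean, atol=1e-10)

    def test_sample_csv_round_trip(self, m1_sample, tmp_path):
        path = tmp_path / "sample.csv"
        m1_sample.to_csv(path)
        back = PosteriorSample.from_csv(path)
        np.testing.assert_allclose(back.draws, m1_sample.draws, atol=1e-9)
        np.testing.assert_allclose(back.deviance, m1_sample.deviance, atol=1e-7)
        assert back.names == m1_sample.names
        assert back.seed == m1_sample.seed
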