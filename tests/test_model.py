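"""Likelihood/prior correctness, sampler determinism, convergence
diagnostics and posterior summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import scatdiet as sd
from scatdiet.design import ModelInput
from scatdiet.exceptions import ConfigurationError, InputError
from scatdiet.model import ParameterState, headline_summary

from conftest import make_draws


def _simple_input(y, pr0=None, species=1, scats=1):
    n = len(y)
    z = np.zeros(n)
    return ModelInput(
        y=np.asarray(y, dtype=np.int8),
        species_index=np.ones(n, dtype=int),
        scat_index=np.ones(n, dtype=int),
        pr0=np.asarray(pr0, float) if pr0 is not None else z,
        pr1=z.copy(), pr2=z.copy(), pr3=z.copy(),
        degradation_day=z.copy(), individual=z.copy(),
        species_labels=[f"s{i}" for i in range(species)],
        scat_labels=[f"c{i}" for i in range(scats)],
    )


def _zero_state(S=1, N=1):
    z = np.zeros(S)
    return ParameterState(beta0=z.copy(), beta1=z.copy(), beta2=z.copy(),
                          beta3=z.copy(), beta4=z.copy(), beta5=0.0, beta6=0.0,
                          alpha=np.zeros(N))


class TestLogLikelihood:
    def test_all_zero_coefficients_give_half_probability(self):
        data = _simple_input([1, 0, 1, 0, 1, 1])
        ll = sd.log_likelihood(_zero_state(), data)
        assert ll == pytest.approx(6 * math.log(0.5))

    def test_saturated_single_row(self):
        data = _simple_input([1])
        st = _zero_state()
        st.beta0[0] = 20.0
        # log sigmoid(20) = -log(1 + e^-20)
        assert sd.log_likelihood(st, data) == pytest.approx(-math.log1p(math.exp(-20)))
        assert sd.log_likelihood(st, data) == pytest.approx(-2.061e-9, rel=1e-3)

    def test_hand_computed_five_row_sum(self):
        """beta0=1, beta1=2, pr0=0.5 -> eta=2 for every row; frozen against
        an independent per-row arithmetic sum."""
        y = [1, 0, 1, 1, 0]
        data = _simple_input(y, pr0=[0.5] * 5)
        st = _zero_state()
        st.beta0[0], st.beta1[0] = 1.0, 2.0
        expected = 0.0
        for yi in y:
            p = 1.0 / (1.0 + math.exp(-2.0))
            expected += math.log(p) if yi else math.log(1 - p)
        assert sd.log_likelihood(st, data) == pytest.approx(expected, abs=1e-12)

    def test_row_permutation_invariance_exact(self, model_input, true_params):
        S, N = model_input.n_species, model_input.n_scats
        st = ParameterState(
            beta0=true_params.beta0, beta1=true_params.beta1, beta2=true_params.beta2,
            beta3=true_params.beta3, beta4=true_params.beta4,
            beta5=true_params.beta5, beta6=true_params.beta6,
            alpha=np.linspace(-1, 1, N),
        )
        ll = sd.log_likelihood(st, model_input)
        rng = np.random.default_rng(0)
        perm = rng.permutation(model_input.n_rows)
        permuted = ModelInput(
            y=model_input.y[perm],
            species_index=model_input.species_index[perm],
            scat_index=model_input.scat_index[perm],
            pr0=model_input.pr0[perm], pr1=model_input.pr1[perm],
            pr2=model_input.pr2[perm], pr3=model_input.pr3[perm],
            degradation_day=model_input.degradation_day[perm],
            individual=model_input.individual[perm],
            species_labels=model_input.species_labels,
            scat_labels=model_input.scat_labels,
        )
        assert sd.log_likelihood(st, permuted) == ll

    def test_extreme_linear_predictor_stays_finite(self):
        data = _simple_input([1, 0])
        st = _zero_state()
        st.beta0[0] = 700.0
        assert np.isfinite(sd.log_likelihood(st, data))

    def test_dimension_mismatch_rejected(self):
        data = _simple_input([1, 0], species=2)
        with pytest.raises(InputError):
            sd.log_likelihood(_zero_state(S=1), data)


class TestLogPrior:
    def test_sigma_alpha_outside_support(self):
        st = _zero_state()
        st.sigma_alpha = 11.0
        assert sd.log_prior(st) == -np.inf

    def test_closed_form_at_hyper_means(self):
        """All hyper-means 0, SDs 1, coefficients at their hyper-means:
        the log prior is a sum of Gaussian and uniform densities with a
        closed form."""
        S, N = 3, 4
        z = np.zeros(S)
        st = ParameterState(beta0=z.copy(), beta1=z.copy(), beta2=z.copy(),
                            beta3=z.copy(), beta4=z.copy(), beta5=0.0, beta6=0.0,
                            alpha=np.zeros(N), mu=np.zeros(5), sigma=np.ones(5),
                            sigma_alpha=1.0)
        expected = (
            5 * norm.logpdf(0, 0, 10)            # hyper-means
            + 5 * math.log(1 / 10)               # sigma_k uniforms
            + 5 * S * norm.logpdf(0, 0, 1)       # betas at their means
            + 2 * norm.logpdf(0, 0, 10)          # beta5, beta6
            + math.log(1 / 10)                   # sigma_alpha uniform
            + N * norm.logpdf(0, 0, 1)           # alphas
        )
        assert sd.log_prior(st) == pytest.approx(expected, abs=1e-12)

    def test_quadratic_decay_in_coefficient_distance(self):
        st = _zero_state(S=1)
        base = sd.log_prior(st)
        st.beta1[0] = 1.0
        d1 = base - sd.log_prior(st)
        st.beta1[0] = 2.0
        d2 = base - sd.log_prior(st)
        assert d2 == pytest.approx(4 * d1)


class TestRunMcmc:
    def test_same_data_and_seed_identical_draws(self, model_input):
        a = sd.run_mcmc(model_input, n_chains=2, n_iter=120, n_burnin=40, seed=5)
        b = sd.run_mcmc(model_input, n_chains=2, n_iter=120, n_burnin=40, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_iteration_budget_validated(self, model_input):
        with pytest.raises(ConfigurationError):
            sd.run_mcmc(model_input, n_iter=100, n_burnin=100, seed=0)

    def test_empty_data_rejected(self):
        empty = _simple_input([])
        with pytest.raises(InputError):
            sd.run_mcmc(empty, seed=0)

    def test_posterior_centres_on_success_fraction(self):
        """Single intercept, 30/60 successes: the posterior mean detection
        probability sits near 0.5."""
        data = _simple_input([1] * 30 + [0] * 30)
        draws = sd.run_mcmc(data, n_chains=2, n_iter=2000, n_burnin=500, seed=8,
                            hierarchical=False, scat_effects=False)
        from scipy.special import expit
        p = expit(draws.pooled("beta0[s0]")).mean()
        assert abs(p - 0.5) < 0.05


class TestGelmanRubin:
    def test_identical_constant_chains_floor_at_one(self):
        arr = np.ones((2, 50, 1))
        d = sd.PosteriorDraws(draws=arr, names=["x"], n_chains=2, n_iter=50,
                              n_burnin=0, seed=0)
        with pytest.warns(UserWarning):
            rep = sd.gelman_rubin(d)
        assert rep.rhat["x"] == 1.0

    def test_iid_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(4, 5000, 1))
        d = sd.PosteriorDraws(draws=arr, names=["x"], n_chains=4, n_iter=5000,
                              n_burnin=0, seed=0)
        rep = sd.gelman_rubin(d)
        assert abs(rep.rhat["x"] - 1.0) < 0.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        arr = np.stack([rng.normal(0, 1, (200, 1)), rng.normal(10, 1, (200, 1))])
        d = sd.PosteriorDraws(draws=arr, names=["x"], n_chains=2, n_iter=200,
                              n_burnin=0, seed=0)
        rep = sd.gelman_rubin(d)
        assert rep.rhat["x"] > 1.1
        assert not rep.converged

    def test_single_chain_rejected(self):
        arr = np.zeros((1, 50, 1))
        d = sd.PosteriorDraws(draws=arr, names=["x"], n_chains=1, n_iter=50,
                              n_burnin=0, seed=0)
        with pytest.raises(InputError):
            sd.gelman_rubin(d)

    def test_split_mode_detects_trend_within_chains(self):
        trend = np.linspace(0, 5, 400).reshape(1, 400, 1)
        arr = np.concatenate([trend, trend])
        d = sd.PosteriorDraws(draws=arr, names=["x"], n_chains=2, n_iter=400,
                              n_burnin=0, seed=0)
        assert sd.gelman_rubin(d, split=True).rhat["x"] > 1.1


class TestSummaries:
    def test_constant_draws(self):
        d = make_draws({"beta5": np.full(100, 3.25)})
        s = sd.summarize_posterior(d)
        row = s.loc["beta5"]
        assert row["mean"] == 3.25 and row["sd"] == 0.0
        assert (row[["q2.5", "q25", "q50", "q75", "q97.5"]] == 3.25).all()

    def test_sequence_mean(self):
        d = make_draws({"beta5": np.arange(1.0, 101.0)})
        assert sd.summarize_posterior(d).loc["beta5", "mean"] == pytest.approx(50.5)

    def test_headline_summary_maps_hyper_means(self, model_input):
        draws = sd.run_mcmc(model_input, n_chains=2, n_iter=150, n_burnin=50, seed=3)
        h = headline_summary(draws)
        assert list(h.index) == ["Day 0/pr fed", "Day 1/pr fed", "Day 2/pr fed",
                                 "Day 3/pr fed", "Degradation", "Cheetah"]
        np.testing.assert_allclose(
            h.loc["Degradation", "mean"],
            sd.summarize_posterior(draws).loc["beta5", "mean"],
        )
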