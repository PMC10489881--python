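"""Model data assembly, likelihoods, priors, sampler correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trailside import glmm
from trailside import synthetic as syn
from trailside import traits as tr
from trailside.families import get_family

from conftest import make_species


def toy_table(n_pairs=2, per=2):
    rows = []
    for p in range(n_pairs):
        for d in (0, 1):
            for i in range(per):
                rows.append({
                    "species": "sp",
                    "pair_id": f"P{p:02d}",
                    "disturbed": d,
                    "quadrat": 1,
                    "elevation_m": 1600.0 + 100.0 * p,
                    "y": 3 + i + d,
                })
    return pd.DataFrame(rows)


class TestBuildModelData:
    def test_design_matrix_layout(self):
        t = toy_table()
        spec = glmm.ModelSpec(response="y", family="negative_binomial")
        data = glmm.build_model_data(t, spec)
        assert data.X.shape == (8, 4)
        assert np.array_equal(data.X[:, 0], np.ones(8))
        assert np.array_equal(data.X[:, 3], data.X[:, 1] * data.X[:, 2])
        assert data.colnames == ["intercept", "b_disturbance", "b_elevation",
                                 "b_interaction"]

    def test_pair_reindexing_contiguous(self):
        t = toy_table()
        t["pair_id"] = t["pair_id"].map({"P00": "A", "P01": "C"})
        data = glmm.build_model_data(
            t, glmm.ModelSpec(response="y", family="negative_binomial")
        )
        assert data.group_labels == ["A", "C"]
        assert set(data.group) == {0, 1}

    def test_constant_disturbance_warns(self):
        t = toy_table()
        t["disturbed"] = 0
        with pytest.warns(UserWarning, match="unidentifiable"):
            glmm.build_model_data(
                t, glmm.ModelSpec(response="y", family="negative_binomial")
            )

    def test_beta_response_must_be_interior(self):
        t = toy_table()
        t["y"] = np.linspace(0.0, 0.9, len(t))
        with pytest.raises(ValueError, match="adjust_unit_interval"):
            glmm.build_model_data(t, glmm.ModelSpec(response="y", family="beta"))

    def test_nb_response_must_be_integer(self):
        t = toy_table()
        t["y"] = t["y"] + 0.25
        with pytest.raises(ValueError, match="round_for_nb"):
            glmm.build_model_data(
                t, glmm.ModelSpec(response="y", family="negative_binomial")
            )

    def test_two_species_rejected(self):
        t = toy_table()
        t.loc[0, "species"] = "other"
        with pytest.raises(ValueError, match="one species"):
            glmm.build_model_data(
                t, glmm.ModelSpec(response="y", family="negative_binomial")
            )


class TestLogLikelihood:
    def _nb_setup(self):
        t = toy_table()
        spec = glmm.ModelSpec(response="y", family="negative_binomial")
        data = glmm.build_model_data(t, spec)
        params = np.zeros(4 + 2 + data.n_groups)
        params[0] = 1.2
        params[1] = -0.3
        params[4] = np.log(2.0)  # shape
        params[5] = np.log(0.5)  # sigma
        params[6:] = [0.1, -0.2]
        return data, spec, params

    def test_pointwise_sums_to_total(self):
        data, spec, params = self._nb_setup()
        total, pointwise = glmm.log_likelihood(params, data, spec)
        assert total == pytest.approx(float(np.sum(pointwise)), abs=1e-12)

    def test_nb_matches_scipy_pmf(self):
        data, spec, params = self._nb_setup()
        _, pointwise = glmm.log_likelihood(params, data, spec)
        beta = params[:4]
        u = params[6:]
        eta = data.X @ beta + u[data.group]
        mu, phi = np.exp(eta), 2.0
        oracle = stats.nbinom.logpmf(data.y, phi, phi / (phi + mu))
        assert np.allclose(pointwise, oracle, atol=1e-10)

    def test_nb_poisson_limit(self):
        # shape -> infinity: NB log-lik approaches the Poisson log-lik
        y = np.arange(10.0)
        eta = np.full(10, 1.3)
        fam = get_family("negative_binomial")
        nb = fam.loglik_pointwise(y, eta, np.log(1e6))
        pois = stats.poisson.logpmf(y, np.exp(eta))
        assert np.max(np.abs(nb - pois)) < 1e-3

    def test_beta_logit_identity(self):
        fam = get_family("beta", link="logit")
        y = np.array([0.2, 0.7])
        ll = fam.loglik_pointwise(y, np.zeros(2), np.log(5.0))
        # beta = 0 with logit link means mu = 0.5 everywhere
        oracle = stats.beta.logpdf(y, 2.5, 2.5)
        assert np.allclose(ll, oracle, atol=1e-10)

    def test_beta_log_link_out_of_range_is_minus_inf(self):
        fam = get_family("beta", link="log")
        ll = fam.loglik_pointwise(np.array([0.4]), np.array([0.5]), 0.0)
        assert np.all(np.isneginf(ll))


class TestLogPosterior:
    def test_prior_decomposition_matches_closed_form(self):
        data, spec, params = TestLogLikelihood()._nb_setup()
        lp = glmm.log_posterior(params, data, spec)
        ll, _ = glmm.log_likelihood(params, data, spec)
        beta, log_aux, log_sigma, u = params[:4], params[4], params[5], params[6:]
        sigma = np.exp(log_sigma)
        expected = (
            np.sum(stats.t.logpdf(beta, 3, scale=10.0))
            + stats.norm.logpdf(log_aux, scale=2.5)
            + np.log(2.0) + stats.t.logpdf(sigma, 3, scale=2.5) + log_sigma
            + np.sum(stats.norm.logpdf(u, scale=sigma))
        )
        assert lp - ll == pytest.approx(float(expected), abs=1e-9)

    def test_prior_only_finite_and_symmetric_in_disturbance(self):
        data, spec, params = TestLogLikelihood()._nb_setup()
        empty = glmm.GLMMData(
            y=np.zeros(0), X=np.zeros((0, 4)), colnames=data.colnames,
            group=np.zeros(0, dtype=int), group_labels=data.group_labels,
        )
        lp_plus = glmm.log_posterior(params, empty, spec)
        flipped = params.copy()
        flipped[1] = -flipped[1]
        lp_minus = glmm.log_posterior(flipped, empty, spec)
        assert np.isfinite(lp_plus)
        assert lp_plus == pytest.approx(lp_minus, abs=1e-12)


class TestSampler:
    def _conjugate_fit(self, seed=0):
        # y ~ Normal(theta, 1), theta ~ Normal(0, tau): closed-form posterior
        rng = np.random.default_rng(7)
        n, tau = 40, 3.0
        y = rng.normal(1.5, 1.0, size=n)
        data = glmm.GLMMData(y=y, X=np.ones((n, 1)), colnames=["intercept"])
        spec = glmm.ModelSpec(
            response="y", family="normal",
            priors=glmm.PriorConfig(beta_prior="normal", beta_scale=tau),
            include_random_intercept=False,
        )
        draws = glmm.sample_posterior(data, spec, chains=3, iterations=2000,
                                      warmup=500, seed=seed, fix_aux=0.0)
        post_var = 1.0 / (1.0 / tau**2 + n)
        post_mean = post_var * y.sum()
        return draws, post_mean, post_var

    def test_conjugate_posterior_mean(self):
        from trailside import diagnostics as dg

        draws, post_mean, post_var = self._conjugate_fit()
        theta = draws.get("intercept")
        ess, _ = dg.ess(theta)
        mcse = theta.std() / np.sqrt(ess)
        assert abs(theta.mean() - post_mean) < 3 * mcse
        assert theta.var() == pytest.approx(post_var, rel=0.2)

    def test_same_seed_identical_draws(self):
        a, _, _ = self._conjugate_fit(seed=5)
        b, _, _ = self._conjugate_fit(seed=5)
        assert np.array_equal(a.draws, b.draws)

    def test_nb_parameter_recovery_single_replicate(self):
        sp = make_species(bD=-0.5, bE=0.0, bDE=0.0)
        design = syn.make_design(syn.SimConfig(seed=21))
        tab = tr.select_per_quadrat(syn.simulate_traits(design, sp, seed=21),
                                    5, seed=21)
        tab["r"] = tr.round_for_nb(tab["height_cm"])
        spec = glmm.ModelSpec(response="r", family="negative_binomial")
        data = glmm.build_model_data(tab, spec)
        draws = glmm.sample_posterior(data, spec, chains=3, iterations=1200,
                                      warmup=400, seed=22)
        e_mean = float(np.mean(data.X[:, 2]))
        eff = draws.pooled("b_disturbance") + draws.pooled("b_interaction") * e_mean
        lo, hi = np.percentile(eff, [2.5, 97.5])
        assert abs(np.mean(eff) - (-0.5)) < 0.2
        assert lo <= -0.5 <= hi

    def test_divergent_init_raises(self):
        data = glmm.GLMMData(y=np.array([np.nan, 1.0]), X=np.ones((2, 1)),
                             colnames=["intercept"])
        spec = glmm.ModelSpec(response="y", family="normal",
                              include_random_intercept=False)
        with pytest.raises((RuntimeError, ValueError)):
            glmm.sample_posterior(data, spec, chains=2, iterations=200,
                                  warmup=50, seed=0)


class TestSummarizeFit:
    def _draws(self, arr, name="b_disturbance"):
        arr = np.asarray(arr, dtype=float)
        return glmm.PosteriorDraws(
            draws=arr[:, :, None], names=[name], seed=0,
            iterations=arr.shape[1], warmup=0, accept_rates={},
        )

    def test_constant_draws(self):
        d = self._draws(np.full((2, 100), 3.0))
        s = glmm.summarize_fit(d, n_obs=10)
        row = s.table.loc["b_disturbance"]
        assert row["mean"] == 3.0 and row["q2.5"] == 3.0 and row["q97.5"] == 3.0
        assert row["effect"]

    def test_standard_normal_ci(self, rng):
        d = self._draws(rng.standard_normal((2, 20000)))
        row = glmm.summarize_fit(d, n_obs=5).table.loc["b_disturbance"]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.08)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.08)
        assert not row["effect"]

    def test_effect_flag_matches_ci_exclusion(self, rng):
        shifted = rng.standard_normal((2, 5000)) + 3.0
        assert glmm.summarize_fit(self._draws(shifted), 5).table.loc[
            "b_disturbance", "effect"
        ]
        skewed = np.abs(rng.standard_normal((2, 5000))) + 0.01
        assert glmm.summarize_fit(self._draws(skewed), 5).table.loc[
            "b_disturbance", "effect"
        ]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            glmm.summarize_fit(self._draws(np.zeros((2, 20))), 5)
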