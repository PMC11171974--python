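"""BYM model: design building, likelihood/CAR oracles, sampler correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from spatqol import model, registry
from spatqol.model import (
    MCMCConfig,
    ModelSpec,
    PriorSpec,
    build_design,
    car_log_kernel,
    fit_model,
    log_likelihood,
    posterior_summaries,
    prior_precision_for_or_interval,
    run_mcmc,
)
from spatqol.weights import WeightMatrix, queen_contiguity
from tests.conftest import point_areas


def chain_weights(n):
    nbrs = [[j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)]
    return WeightMatrix(
        ids=[f"A{i}" for i in range(n)],
        neighbours=nbrs,
        weights=[np.ones(len(x)) for x in nbrs],
        kind="custom",
    )


def tiny_records(n=30, n_areas=2, seed=0, year_range=(2015, 2021)):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "area_id": [f"A{i % n_areas}" for i in range(n)],
            "year": rng.integers(year_range[0], year_range[1] + 1, n),
            "poor_qol": rng.integers(0, 2, n),
        }
    )


class TestBuildDesign:
    def test_binary_covariate_dummy_column(self):
        W = chain_weights(2)
        rec = tiny_records(3)
        rec["grp"] = ["other", "ref", "other"]
        spec = ModelSpec(covariates={"grp": {"levels": ["ref", "other"], "ref": "ref"}})
        data = build_design(rec, spec, W)
        assert data.X[:, 0].tolist() == [1.0, 0.0, 1.0]

    def test_year_centring(self):
        W = chain_weights(2)
        rec = tiny_records(40)
        spec = ModelSpec(covariates={})
        data = build_design(rec, spec, W)
        assert set(data.t) <= set(range(-3, 4))
        assert set(data.t**2) <= {0.0, 1.0, 4.0, 9.0}

    def test_full_covariate_set_slope_count(self):
        # 3 (age) + 3 (nccn) + 2 (psa) + 1 (institution) + 2 (accessibility)
        _, W, _, _, pats = registry.simulate_registry(
            registry.SimulationConfig(n_patients=500, seed=1)
        )
        data = build_design(pats, ModelSpec(), W)
        assert data.X.shape[1] == 11

    def test_unknown_level_named(self):
        W = chain_weights(2)
        rec = tiny_records(3)
        rec["grp"] = ["ref", "weird", "ref"]
        spec = ModelSpec(covariates={"grp": {"levels": ["ref", "other"], "ref": "ref"}})
        with pytest.raises(ValueError, match="weird"):
            build_design(rec, spec, W)


class TestLogLikelihood:
    def test_fifty_fifty(self):
        total, pw = log_likelihood([1, 0], [0.0, 0.0])
        assert total == pytest.approx(2 * np.log(0.5), abs=1e-10)

    def test_saturated_limit(self):
        _, pw = log_likelihood([1], [500.0])
        assert pw[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_bernoulli_pmf_product(self, rng):
        y = rng.integers(0, 2, 20)
        eta = rng.normal(0, 2, 20)
        total, _ = log_likelihood(y, eta)
        oracle = sum(
            np.log(stats.bernoulli.pmf(yi, expit(e))) for yi, e in zip(y, eta)
        )
        assert total == pytest.approx(oracle, abs=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([1], [np.nan])


class TestCarKernel:
    def test_zero_field(self):
        W = chain_weights(5)
        assert car_log_kernel(np.zeros(5), W, 2.0) == pytest.approx(2.0 * np.log(2.0))

    def test_two_area_antisymmetric(self):
        W = chain_weights(2)
        a = 0.7
        assert car_log_kernel(np.array([a, -a]), W, 1.0) == pytest.approx(-2 * a**2)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pairwise_loop_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        adj = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
        adj = adj + adj.T
        nbrs = [np.flatnonzero(adj[j]) for j in range(n)]
        W = WeightMatrix(
            ids=[str(j) for j in range(n)], neighbours=nbrs,
            weights=[np.ones(len(x)) for x in nbrs], kind="custom",
        )
        u = rng.normal(0, 1, n)
        u -= u.mean()
        tau = float(rng.uniform(0.5, 3))
        ncomp, _ = W.components()
        pair_sum = sum(
            adj[j, k] * (u[j] - u[k]) ** 2 for j in range(n) for k in range(j + 1, n)
        )
        oracle = 0.5 * (n - ncomp) * np.log(tau) - 0.5 * tau * pair_sum
        assert car_log_kernel(u, W, tau) == pytest.approx(oracle, abs=1e-10)


class TestPriorCalibration:
    def test_published_precision_recovered(self):
        # 95% prior mass for the OR in (0.1, 10) <-> precision (1.96/ln10)^2
        prec = prior_precision_for_or_interval(0.1, 10.0, 0.95)
        assert prec == pytest.approx((stats.norm.ppf(0.975) / np.log(10)) ** 2, abs=1e-9)
        assert round(prec, 3) == 0.725


class TestSampler:
    def test_prior_only_posterior_sd_matches_prior(self):
        """With the likelihood switched off the sampler must reproduce the
        Normal(0, 1/0.725) coefficient prior: sd 1.1744."""
        _, W, _, _, pats = registry.simulate_registry(
            registry.SimulationConfig(n_rows=2, n_cols=2, n_patients=40, seed=4)
        )
        spec = ModelSpec(covariates={"institution": {"levels": ["Private", "Public"], "ref": "Private"}})
        mc = MCMCConfig(
            n_iter=55_000, burn_in=5_000, thin=1, n_chains=1,
            likelihood_weight=0.0, tau_u_fixed=1.0, tau_v_fixed=1.0,
        )
        draws = fit_model(pats, W, spec=spec, config=mc, base_seed=8)
        sd = draws.stacked("institution[Public]").std(ddof=1)
        assert sd == pytest.approx(1 / np.sqrt(0.725), rel=0.05)

    def test_recentring_contract(self):
        _, W, _, _, pats = registry.simulate_registry(
            registry.SimulationConfig(n_rows=2, n_cols=3, n_patients=120, seed=5)
        )
        mc = MCMCConfig(n_iter=400, burn_in=100, thin=1, n_chains=1)
        draws = fit_model(pats, W, spec=ModelSpec(covariates={}), config=mc, base_seed=2)
        usum = np.abs(draws.chains[0].params["u"].sum(axis=1))
        assert (usum < 1e-8).all()

    def test_streaming_determinism_under_longer_run(self):
        _, W, _, _, pats = registry.simulate_registry(
            registry.SimulationConfig(n_rows=2, n_cols=3, n_patients=100, seed=6)
        )
        spec = ModelSpec(covariates={})
        short = MCMCConfig(n_iter=300, burn_in=0, thin=1, n_chains=1)
        long = MCMCConfig(n_iter=600, burn_in=0, thin=1, n_chains=1)
        a = fit_model(pats, W, spec=spec, config=short, base_seed=3)
        b = fit_model(pats, W, spec=spec, config=long, base_seed=3)
        for name in ("alpha", "tau_u", "tau_v"):
            assert np.array_equal(
                a.chains[0].params[name], b.chains[0].params[name][:300]
            )

    def test_tau_gibbs_matches_full_conditional_with_frozen_field(self):
        """Holding u (and v) fixed, the tau draws must follow
        Gamma(a + (J-c)/2, b + quad/2) exactly (QQ agreement)."""
        _, W, _, _, pats = registry.simulate_registry(
            registry.SimulationConfig(n_rows=2, n_cols=3, n_patients=60, seed=9)
        )
        rng = np.random.default_rng(0)
        u_fix = rng.normal(0, 1, 6)
        u_fix -= u_fix.mean()
        v_fix = rng.normal(0, 0.5, 6)
        mc = MCMCConfig(
            n_iter=4000, burn_in=0, thin=1, n_chains=1,
            freeze_u=u_fix, freeze_v=v_fix,
        )
        priors = PriorSpec()
        draws = fit_model(pats, W, spec=ModelSpec(covariates={}), priors=priors,
                          config=mc, base_seed=12)
        A = W.to_sparse().toarray()
        quad_u = sum(
            A[j, k] * (u_fix[j] - u_fix[k]) ** 2
            for j in range(6) for k in range(j + 1, 6)
        )
        a_u, b_u = priors.tau_u_prior
        dist_u = stats.gamma(a=a_u + (6 - 1) / 2, scale=1 / (b_u + quad_u / 2))
        tu = np.sort(draws.stacked("tau_u"))
        qq = dist_u.ppf((np.arange(1, 4001) - 0.5) / 4000)
        assert np.corrcoef(tu, qq)[0, 1] > 0.99
        ks = stats.kstest(tu, dist_u.cdf).pvalue
        assert ks > 0.001

    def test_isolated_area_rejected_without_override(self):
        import warnings

        from spatqol.weights import distance_band

        areas = point_areas([(0, 0), (1, 0), (9, 0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = distance_band(areas, 1.5)
        rec = tiny_records(30, n_areas=3)
        rec["area_id"] = [f"P{i % 3}" for i in range(30)]
        with pytest.raises(ValueError, match="isolated"):
            fit_model(rec, W, spec=ModelSpec(covariates={}), config=MCMCConfig(n_iter=10, burn_in=5))


class TestPosteriorSummaries:
    def _draws_from(self, values, name="grp[b]"):
        chain = model.ChainDraws(
            params={name: np.asarray(values, dtype=float)},
            acceptance={}, seed_entropy=0, loglik_matrix=None,
            waic_acc=None,
        )
        return model.PosteriorDraws(chains=[chain], colnames=[name], config=MCMCConfig(n_iter=2, burn_in=1))

    def test_zero_draws_give_unit_or(self):
        summ = posterior_summaries(self._draws_from(np.zeros(100)))
        row = summ[summ.coefficient == "grp[b]"].iloc[0]
        assert (row.or_lo, row["or"], row.or_hi) == (1.0, 1.0, 1.0)

    def test_degenerate_normal_draws(self, rng):
        summ = posterior_summaries(self._draws_from(rng.normal(np.log(2), 1e-6, 5000)))
        assert summ.iloc[0]["or"] == pytest.approx(2.0, rel=1e-4)

    def test_quantiles_match_sort_index_oracle(self, rng):
        vals = rng.normal(0, 1, 101)
        summ = posterior_summaries(self._draws_from(vals))
        srt = np.sort(vals)
        # with 101 draws the 2.5/50/97.5% empirical quantiles are exact order stats
        assert summ.iloc[0]["or"] == pytest.approx(np.exp(srt[50]), rel=1e-12)
        assert summ.iloc[0]["or_lo"] == pytest.approx(np.exp(srt[2] + 0.5 * (srt[3] - srt[2])), rel=1e-9)


class TestPosteriorCorrectness:
    def test_mcmc_matches_grid_integration_on_tiny_instance(self):
        """Two areas, 10 patients, intercept + BYM effects with fixed
        precisions: the MCMC marginal for the total per-area log-odds must
        match dense grid integration (TV < 0.05)."""
        records = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(10)],
                "area_id": ["A0"] * 5 + ["A1"] * 5,
                "year": [2018] * 10,
                "poor_qol": [1, 1, 1, 0, 0, 1, 0, 0, 0, 0],
            }
        )
        W = chain_weights(2)
        tau_u, tau_v, kappa = 1.0, 4.0, 0.725
        mc = MCMCConfig(
            n_iter=210_000, burn_in=10_000, thin=1, n_chains=1,
            tau_u_fixed=tau_u, tau_v_fixed=tau_v,
        )
        spec = ModelSpec(covariates={}, include_time=False)
        draws = fit_model(records, W, spec=spec, config=mc, base_seed=21)
        c = draws.chains[0].params
        # eta_j = alpha + u_j + v_j is the identified quantity
        eta0 = c["alpha"] + c["u"][:, 0] + c["v"][:, 0]

        # dense grid over (alpha, a, v0, v1) with u = (a, -a)
        alpha = np.linspace(-5, 5, 121)[:, None, None, None]
        a = np.linspace(-3, 3, 81)[None, :, None, None]
        v0 = np.linspace(-2.5, 2.5, 61)[None, None, :, None]
        v1 = np.linspace(-2.5, 2.5, 61)[None, None, None, :]
        e0 = alpha + a + v0
        e1 = alpha - a + v1
        loglik = (
            3 * e0 - 5 * np.logaddexp(0, e0) + 1 * e1 - 5 * np.logaddexp(0, e1)
        )
        logprior = (
            -0.5 * kappa * alpha**2
            - 0.5 * tau_u * (2 * a) ** 2
            - 0.5 * tau_v * (v0**2 + v1**2)
        )
        post = np.exp(loglik + logprior - (loglik + logprior).max())
        # marginal of eta0 = alpha + a + v0 on a common binning
        bins = np.linspace(-4, 4, 41)
        e0_flat = np.broadcast_to(e0, post.shape).ravel()
        w_flat = post.ravel()
        grid_hist, _ = np.histogram(e0_flat, bins=bins, weights=w_flat)
        grid_hist = grid_hist / grid_hist.sum()
        mcmc_hist, _ = np.histogram(eta0, bins=bins)
        mcmc_hist = mcmc_hist / mcmc_hist.sum()
        tv = 0.5 * np.abs(grid_hist - mcmc_hist).sum()
        assert tv < 0.05
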