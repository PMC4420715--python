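import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from pacfcov.bayes_fit import (
    DICReport,
    LikelihoodEngine,
    MCMCConfig,
    ModelSpec,
    PriorSpec,
    compute_dic,
    log_marginal_likelihood,
    run_mcmc,
    split_rhat,
)
from pacfcov.covariance_model import CovarianceParams, build_subject_covariance
from pacfcov.interface import LongitudinalDataset
from pacfcov.mean_model import CLMParams, LinearMean, LMMParams, clm_mean_vector, lmm_marginal_covariance
from pacfcov.synthetic import simulate_dataset

from conftest import make_reduced_scenario, reduced_spec


def _one_point_dataset(y=0.0):
    return LongitudinalDataset(
        ids=[1], times=[[1]], y=[[y]], dose=[0], dropout=[5.0], T=5, resolution=1.0
    )


def _unit_cov(T=5):
    return CovarianceParams(
        family="stationary", a=1, gamma0=[0.0], gamma1=[0.0], alpha=[0.0, 0.0],
        sigma_b=0.0, var_scale=T,
    )


class TestLogMarginalLikelihood:
    def test_standard_normal_point(self):
        ll = log_marginal_likelihood(
            _one_point_dataset(0.0), LinearMean(beta=np.zeros(4)), _unit_cov()
        )
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_additivity_over_subjects(self):
        sc = make_reduced_scenario(N=12, T=10, seed=6)
        ds = simulate_dataset(sc)
        half = 6

        def subset(sl):
            return LongitudinalDataset(
                ids=ds.ids[sl], times=ds.times[sl], y=ds.y[sl],
                dose=ds.dose[sl], dropout=ds.dropout[sl], T=ds.T,
                resolution=ds.resolution,
            )

        full = log_marginal_likelihood(ds, sc.mean, sc.cov)
        a = log_marginal_likelihood(subset(slice(None, half)), sc.mean, sc.cov)
        b = log_marginal_likelihood(subset(slice(half, None)), sc.mean, sc.cov)
        assert full == pytest.approx(a + b, abs=1e-8)

    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(31)
        for trial in range(5):
            sc = make_reduced_scenario(N=5, T=10, seed=100 + trial)
            ds = simulate_dataset(sc)
            cov = CovarianceParams(
                family="stationary", a=2,
                gamma0=[rng.uniform(0.3, 1.5)], gamma1=[rng.uniform(-0.5, 0)],
                alpha=rng.uniform(-0.5, 1.5, 2), sigma_b=rng.uniform(0.2, 2.0),
                var_scale=10,
            )
            ll = log_marginal_likelihood(ds, sc.mean, cov)
            oracle = 0.0
            for i in range(ds.n_subjects):
                t = ds.times[i]
                mu = clm_mean_vector(sc.mean, t, ds.dose[i], ds.dropout[i])
                S = build_subject_covariance(cov, None, t, T=ds.T)
                oracle += multivariate_normal.logpdf(ds.y[i], mu, S)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_lmm_matches_dense_oracle(self):
        sc = make_reduced_scenario(N=5, T=10, seed=55)
        ds = simulate_dataset(sc)
        lmm = LMMParams(lambda_=-0.3, sigma0=2.0, sigma_e=1.0, sigma_eps=1.5,
                        time_scale=5.0)
        ll = log_marginal_likelihood(ds, sc.mean, lmm)
        oracle = 0.0
        for i in range(ds.n_subjects):
            t = ds.times[i]
            mu = clm_mean_vector(sc.mean, t, ds.dose[i], ds.dropout[i])
            oracle += multivariate_normal.logpdf(
                ds.y[i], mu, lmm_marginal_covariance(lmm, t)
            )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_engine_agrees_with_reference(self):
        sc = make_reduced_scenario(N=20, T=10, seed=8)
        ds = simulate_dataset(sc)
        spec = reduced_spec(a=2)
        engine = LikelihoodEngine(ds, spec)
        ll_ref = log_marginal_likelihood(ds, sc.mean, sc.cov)
        ll_eng = engine.loglik(sc.mean.theta, engine.sigma_stack(sc.cov))
        assert ll_eng == pytest.approx(ll_ref, abs=1e-8)
        # the cached-component route gives the same stack
        comps = engine.pacf_comps(sc.cov)
        np.testing.assert_allclose(
            engine.sigma_from_comps(comps), engine.sigma_stack(sc.cov), atol=1e-12
        )


class TestRunMcmc:
    def test_same_seed_identical_chains(self, small_dataset):
        cfg = MCMCConfig(iterations=30, burn_in=30, chains=2, seed=3)
        s1 = run_mcmc(small_dataset, reduced_spec(), PriorSpec(), cfg)
        s2 = run_mcmc(small_dataset, reduced_spec(), PriorSpec(), cfg)
        np.testing.assert_array_equal(s1.draws, s2.draws)
        np.testing.assert_array_equal(s1.loglik, s2.loglik)

    def test_zero_iterations_returns_initial_state(self, small_dataset):
        cfg = MCMCConfig(iterations=0, burn_in=0, chains=2, seed=3)
        s = run_mcmc(small_dataset, reduced_spec(), PriorSpec(), cfg)
        assert s.draws.shape[1] == 1
        # both chains start from the same deterministic initialization
        np.testing.assert_array_equal(s.draws[0], s.draws[1])

    def test_draws_satisfy_constraints(self, small_fit):
        gamma1 = small_fit.param("gamma_1")
        assert np.all(gamma1 <= 0)
        assert np.all(small_fit.param("sigma_b") > 0)
        assert np.all(small_fit.param("sigma_b") < PriorSpec().sd_upper)

    def test_posterior_dataframe_layout(self, small_fit):
        df = small_fit.to_dataframe()
        assert {"chain", "draw", "loglik"} <= set(df.columns)
        assert len(df) == small_fit.n_chains * small_fit.n_draws
        for name in small_fit.names:
            assert name in df.columns

    def test_unpack_roundtrip(self, small_fit):
        mean, cov = small_fit.unpack(small_fit.pooled()[0])
        assert isinstance(mean, CLMParams)
        assert cov.family == "stationary"
        assert cov.gamma1[0] <= 0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=-1)
        with pytest.raises(ValueError):
            MCMCConfig(chains=0)
        with pytest.raises(ValueError):
            PriorSpec(normal_sd=-1.0)


class TestDIC:
    def test_identity(self, small_fit, small_dataset):
        rep = compute_dic(small_fit, small_dataset)
        assert rep.DIC == pytest.approx(rep.Dbar + rep.pD, abs=1e-10)
        assert rep.pD == pytest.approx(rep.Dbar - rep.Dhat, abs=1e-10)
        assert rep.pD > 0  # a fitted model has positive effective parameters

    def test_single_draw_degenerate(self, small_dataset):
        cfg = MCMCConfig(iterations=1, burn_in=20, chains=1, seed=5)
        s = run_mcmc(small_dataset, reduced_spec(), PriorSpec(), cfg)
        rep = compute_dic(s, small_dataset)
        assert rep.pD == pytest.approx(0.0, abs=1e-6)
        assert rep.DIC == pytest.approx(rep.Dbar, abs=1e-6)

    def test_report_dict(self):
        rep = DICReport(Dbar=100.0, Dhat=90.0)
        assert rep.as_dict() == {"Dbar": 100.0, "Dhat": 90.0, "pD": 10.0, "DIC": 110.0}


class TestDiagnostics:
    def test_split_rhat_iid_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((2, 500, 3))
        r = split_rhat(draws)
        assert np.all(np.abs(r - 1.0) < 0.05)

    def test_split_rhat_detects_divergence(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((2, 500, 1))
        draws[1] += 10.0
        assert split_rhat(draws)[0] > 2.0

    def test_acceptance_rates_recorded(self, small_fit):
        assert set(small_fit.acceptance) == {"gamma", "alpha", "sigma_b"}
        for v in small_fit.acceptance.values():
            assert 0.0 < v < 1.0

    def test_trace_plot_written(self, small_fit, tmp_path):
        out = tmp_path / "trace.png"
        small_fit.plot_trace(names=["gamma_0", "sigma_b"], path=out)
        assert out.stat().st_size > 0


class TestDropoutIndependentCollapse:
    def test_clm_recovers_zero_dropout_slopes(self):
        # truth has theta_k1 = 0 for all k: the fitted CLM should find the
        # dropout-slope block indistinguishable from zero
        from dataclasses import replace as _replace

        sc = make_reduced_scenario(N=120, T=10, seed=64)
        theta0 = sc.mean.theta.copy()
        theta0[1::2] = 0.0
        sc = _replace(sc, mean=_replace(sc.mean, theta=theta0))
        ds = simulate_dataset(sc)
        s = run_mcmc(
            ds, reduced_spec(a=2), PriorSpec(),
            MCMCConfig(iterations=250, burn_in=250, chains=2, seed=64),
        )
        sm = s.summary()
        for k in range(4):
            name = f"theta_{k}1"
            assert abs(sm.loc[name, "mean"]) < 3.0 * sm.loc[name, "sd"], name
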