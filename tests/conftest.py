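"""Shared fixtures: reduced-size synthetic scenarios and a cached short fit."""

from dataclasses import replace

import numpy as np
import pytest

from pacfcov.bayes_fit import MCMCConfig, ModelSpec, PriorSpec, run_mcmc
from pacfcov.covariance_model import CovarianceParams
from pacfcov.mean_model import CLMParams
from pacfcov.synthetic import SimScenario, simulate_dataset

REDUCED_TRUTH = {
    "gamma_0": 0.9,
    "gamma_1": -0.15,
    "alpha_0": 2.0,
    "alpha_1": -0.8,
    "sigma_b": 1.5,
    "theta_00": 20.0,
    "theta_01": 3.0,
    "theta_10": -3.0,
    "theta_11": 2.0,
    "theta_20": -1.0,
    "theta_21": 1.0,
    "theta_30": 1.0,
    "theta_31": -1.0,
}


def make_reduced_scenario(N=100, T=10, a=2, seed=0, **cov_overrides) -> SimScenario:
    """Small stationary CLM scenario for fast fitting tests."""
    cov = CovarianceParams(
        family="stationary",
        a=a,
        gamma0=[REDUCED_TRUTH["gamma_0"]],
        gamma1=[REDUCED_TRUTH["gamma_1"]],
        alpha=[REDUCED_TRUTH["alpha_0"], REDUCED_TRUTH["alpha_1"]],
        sigma_b=REDUCED_TRUTH["sigma_b"],
        var_scale=T,
    )
    if cov_overrides:
        cov = replace(cov, **cov_overrides)
    theta = np.array([REDUCED_TRUTH[f"theta_{k}{j}"] for k in range(4) for j in range(2)])
    mean = CLMParams(theta=theta, dropout_center=28.0, dropout_scale=15.0, time_scale=5.0)
    return SimScenario(
        name="reduced",
        N=N,
        T=T,
        cov=cov,
        mean=mean,
        dropout_support=np.arange(4, T + 1),
        resolution=4.0,
        seed=seed,
    )


def reduced_spec(a=2, T=10, **kwargs) -> ModelSpec:
    return ModelSpec(
        covariance="stationary",
        mean="clm",
        a=a,
        var_scale=T,
        dropout_center=28.0,
        dropout_scale=15.0,
        time_scale=5.0,
        **kwargs,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(make_reduced_scenario(N=80, T=10, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short but usable stationary CLM fit, shared across test modules."""
    return run_mcmc(
        small_dataset,
        reduced_spec(a=2),
        PriorSpec(),
        MCMCConfig(iterations=200, burn_in=200, chains=2, seed=7),
    )
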