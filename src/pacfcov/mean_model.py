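"""Mean structures: plain linear model, conditional linear model (CLM) in the
observed dropout time, and the random intercept/slope LMM comparator.

The CLM makes each mean coefficient an affine function of the centered,
rescaled dropout time, beta_k(d) = theta_k0 + theta_k1 * d*, with
d* = (d - dbar)/dropout_scale.  The linear predictor is

    mu(t) = beta0(d) + beta1(d) * (t-1)/time_scale
          + beta2(d) * dose + beta3(d) * dose * (t-1)/time_scale

so beta1 is the change per ``time_scale`` grid units (a year when the grid is
4-weekly and time_scale = 13) and t = 1 is enrollment.  Setting all theta_k1
to zero recovers a dropout-free linear model.

The LMM comparator parameterizes the random-effect covariance G through a
modified Cholesky decomposition, b1 = lambda * b0 + e: sampling (lambda,
sigma0, sigma_e) guarantees G positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CLMParams",
    "LMMParams",
    "LinearMean",
    "clm_coefficients",
    "clm_mean_vector",
    "clm_design_matrix",
    "linear_design_matrix",
    "lmm_marginal_covariance",
]


@dataclass
class CLMParams:
    """Conditional linear model coefficients.

    theta : length-8 vector (theta00, theta01, theta10, theta11, theta20,
        theta21, theta30, theta31); the even entries are intercepts of
        beta_k(d) and the odd entries its slopes in d*.
    dropout_center : sample mean of the observed dropout times (same units
        as d, e.g. weeks).
    dropout_scale : positive divisor applied after centering (default 100
        for dropout in weeks).
    time_scale : grid units per slope unit (default 13, i.e. per year on a
        4-week grid).
    """

    theta: np.ndarray
    dropout_center: float
    dropout_scale: float = 100.0
    time_scale: float = 13.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (8,):
            raise ValueError("theta must have exactly 8 entries")
        if self.dropout_scale <= 0:
            raise ValueError("dropout_scale must be positive")

    def rescale_dropout(self, d) -> np.ndarray:
        return (np.asarray(d, dtype=float) - self.dropout_center) / self.dropout_scale


def clm_coefficients(params: CLMParams, d) -> np.ndarray:
    """beta_k(d) = theta_k0 + theta_k1 * d* for k = 0..3.

    Returns shape (4,) for scalar d, else (len(d), 4).
    """
    dstar = params.rescale_dropout(d)
    th = params.theta.reshape(4, 2)
    out = th[:, 0] + np.multiply.outer(dstar, th[:, 1])
    return out


def clm_design_matrix(params: CLMParams, times, dose: float, d: float) -> np.ndarray:
    """Design matrix mapping theta (8-vector) to the subject's mean vector."""
    times = np.asarray(times, dtype=float)
    s = (times - 1.0) / params.time_scale
    dstar = float(params.rescale_dropout(d))
    base = np.column_stack([np.ones_like(s), s, dose * np.ones_like(s), dose * s])
    X = np.empty((len(times), 8))
    X[:, 0::2] = base
    X[:, 1::2] = base * dstar
    return X


def linear_design_matrix(times, dose: float, time_scale: float = 13.0) -> np.ndarray:
    """Dropout-free design (intercept, slope, dose, dose x slope)."""
    times = np.asarray(times, dtype=float)
    s = (times - 1.0) / time_scale
    return np.column_stack([np.ones_like(s), s, dose * np.ones_like(s), dose * s])


def clm_mean_vector(params: CLMParams, times, dose: float, d: float) -> np.ndarray:
    """Mean vector mu(t) over grid ``times`` for a subject with covariates
    (dose, dropout time d); the random intercept lives in the covariance."""
    return clm_design_matrix(params, times, dose, d) @ params.theta


@dataclass
class LinearMean:
    """Dropout-free linear mean: beta = (intercept, slope, dose, dose x slope)."""

    beta: np.ndarray
    time_scale: float = 13.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must have exactly 4 entries")

    def mean_vector(self, times, dose: float) -> np.ndarray:
        return linear_design_matrix(times, dose, self.time_scale) @ self.beta


@dataclass
class LMMParams:
    """Random intercept/slope LMM with modified-Cholesky G.

    b1 = lambda_ * b0 + e with b0 ~ N(0, sigma0^2), e ~ N(0, sigma_e^2)
    implies G = [[sigma0^2, lambda sigma0^2],
                 [lambda sigma0^2, lambda^2 sigma0^2 + sigma_e^2]],
    positive definite whenever sigma0, sigma_e > 0.  Residuals are iid
    N(0, sigma_eps^2).
    """

    lambda_: float
    sigma0: float
    sigma_e: float
    sigma_eps: float
    time_scale: float = 13.0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.sigma_e <= 0 or self.sigma_eps <= 0:
            raise ValueError("sigma0, sigma_e, sigma_eps must be positive")

    @property
    def G(self) -> np.ndarray:
        s0sq = self.sigma0**2
        s01 = self.lambda_ * s0sq
        s1sq = self.lambda_**2 * s0sq + self.sigma_e**2
        return np.array([[s0sq, s01], [s01, s1sq]])


def lmm_marginal_covariance(params: LMMParams, times) -> np.ndarray:
    """Marginal covariance Z G Z' + sigma_eps^2 I at grid ``times``,
    with random-effect design rows z_t = (1, (t-1)/time_scale)."""
    times = np.asarray(times, dtype=float)
    s = (times - 1.0) / params.time_scale
    Z = np.column_stack([np.ones_like(s), s])
    return Z @ params.G @ Z.T + params.sigma_eps**2 * np.eye(len(times))
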