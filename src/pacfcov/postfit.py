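"""Post-fit summaries: Bayesian-bootstrap marginal covariate effects and the
chi-square posterior predictive check.

Marginal effects leave the dropout-time distribution unspecified: at each
posterior draw, Dirichlet(1,...,1) weights are drawn independently over each
dose group's observed dropout times and the dropout-conditional coefficients
beta(d) are averaged under them.  The reported 4-vector is

    (high-group intercept, high-group slope,
     dose effect = low marginal intercept - high marginal intercept,
     dose x slope = low marginal slope - high marginal slope).

The PPC replicates the full observation process per retained draw: dropout
times resampled from the empirical distribution (within dose group),
measurement times rebuilt from pooled observed gap times, responses drawn
from the model, and the Gaussian quadratic-form discrepancy compared between
replicated and observed data with random effects integrated out.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cho_factor

from .bayes_fit import PosteriorSamples
from .covariance_model import evaluate_pacf, evaluate_variance
from .interface import LongitudinalDataset
from .mean_model import CLMParams, clm_mean_vector
from .pacf_core import corr_for_times

__all__ = [
    "MarginalEffects",
    "PPCReport",
    "bayesian_bootstrap_weights",
    "marginal_effects",
    "ppc_chi2",
]


@dataclass
class MarginalEffects:
    """Per-draw marginal effect 4-vectors with posterior summaries."""

    draws: np.ndarray  # (n_draws, 4)
    labels: tuple = ("intercept", "slope", "dose", "dose_x_slope")

    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def interval(self, level: float = 0.95) -> np.ndarray:
        lo = (1.0 - level) / 2.0 * 100.0
        return np.percentile(self.draws, [lo, 100.0 - lo], axis=0).T

    def summary_table(self) -> dict:
        med = self.median()
        ci = self.interval()
        return {
            lab: {"median": float(m), "q2.5": float(l), "q97.5": float(u)}
            for lab, m, (l, u) in zip(self.labels, med, ci)
        }


@dataclass
class PPCReport:
    """chi-square posterior predictive check."""

    chi2_rep: np.ndarray
    chi2_obs: np.ndarray

    @property
    def ppp(self) -> float:
        """Fraction of draws whose replicated discrepancy exceeds the
        observed one; ~0.5 indicates adequate fit."""
        return float(np.mean(self.chi2_rep > self.chi2_obs))


def bayesian_bootstrap_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet(1,...,1) draw: nonnegative weights summing to one."""
    if n < 1:
        raise ValueError("need at least one observation to weight")
    return rng.dirichlet(np.ones(n))


def _clm_from_draw(samples: PosteriorSamples, theta: np.ndarray) -> CLMParams:
    return CLMParams(
        theta=theta,
        dropout_center=samples.dropout_center,
        dropout_scale=samples.spec.dropout_scale,
        time_scale=samples.spec.time_scale,
    )


def marginal_effects(
    samples: PosteriorSamples,
    dropout_times_by_group: dict,
    rng: np.random.Generator,
) -> MarginalEffects:
    """Bayesian-bootstrap marginal covariate effects from a fitted CLM.

    Parameters
    ----------
    samples : PosteriorSamples from a model with ``mean='clm'``.
    dropout_times_by_group : mapping {0: dropout times of the dose=0 group,
        1: dropout times of the dose=1 group}, in raw units.
    rng : generator driving the Dirichlet draws (fresh weights per draw,
        independent across the two groups).
    """
    if samples.spec.mean != "clm":
        raise ValueError("marginal effects require a conditional linear model fit")
    d_high = np.asarray(dropout_times_by_group[0], dtype=float)
    d_low = np.asarray(dropout_times_by_group[1], dtype=float)
    if d_high.size == 0 or d_low.size == 0:
        raise ValueError("both dose groups must have observed dropout times")

    theta_idx = [samples.names.index(f"theta_{k}{j}") for k in range(4) for j in range(2)]
    thetas = samples.pooled()[:, theta_idx]  # (n_draws, 8)
    n_draws = thetas.shape[0]
    center, scale = samples.dropout_center, samples.spec.dropout_scale
    ds_high = (d_high - center) / scale
    ds_low = (d_low - center) / scale

    # beta_k(d_i) per draw: (n_draws, n_i, 4)
    b_high = thetas[:, None, 0::2] + ds_high[None, :, None] * thetas[:, None, 1::2]
    b_low = thetas[:, None, 0::2] + ds_low[None, :, None] * thetas[:, None, 1::2]

    w_high = rng.dirichlet(np.ones(len(d_high)), size=n_draws)
    w_low = rng.dirichlet(np.ones(len(d_low)), size=n_draws)
    avg_high = np.einsum("gi,gik->gk", w_high, b_high)
    avg_low = np.einsum("gi,gik->gk", w_low, b_low)

    out = np.empty((n_draws, 4))
    out[:, 0] = avg_high[:, 0]
    out[:, 1] = avg_high[:, 1]
    out[:, 2] = (avg_low[:, 0] + avg_low[:, 2]) - avg_high[:, 0]
    out[:, 3] = (avg_low[:, 1] + avg_low[:, 3]) - avg_high[:, 1]
    return MarginalEffects(draws=out)


def _chi2_discrepancy(y_list, mu_list, cov_list) -> float:
    total = 0.0
    for y, mu, S in zip(y_list, mu_list, cov_list):
        r = y - mu
        total += float(r @ cho_solve(cho_factor(S, lower=True), r))
    return total


def ppc_chi2(
    samples: PosteriorSamples,
    data: LongitudinalDataset,
    rng: np.random.Generator,
    n_draws: int = 200,
) -> PPCReport:
    """Posterior predictive check with the chi-square discrepancy.

    Per retained draw: (1) replicated dropout times are sampled from the
    empirical dropout distribution within each subject's dose group; (2)
    replicated measurement times start at grid point 1 and accumulate gaps
    resampled (pooled across subjects) until the dropout time; (3) responses
    are simulated from the model at those times; the discrepancy
    sum_i r_i' Sigma_i^-1 r_i (random effects integrated out) is computed for
    both replicated and observed data and ``ppp`` is the exceedance fraction.
    """
    gaps = np.sort(data.gap_times())  # canonical order: subject-order invariant
    if gaps.size == 0:
        raise ValueError("no observed gap times to resample")
    pooled = samples.pooled()
    take = np.linspace(0, pooled.shape[0] - 1, min(n_draws, pooled.shape[0])).astype(int)
    # per-(draw, subject) child streams keyed by subject id, so the result is
    # invariant to subject ordering for a fixed seed
    base_entropy = int(rng.integers(2**63))

    def _subject_rng(k: int, sid) -> np.random.Generator:
        sid_hash = zlib.crc32(str(sid).encode())
        return np.random.default_rng(np.random.SeedSequence((base_entropy, k, sid_hash)))

    dose = data.dose
    dgrid = data.dropout_grid()
    draw_pool = {
        g: np.sort(data.dropout[dose == g]) for g in (0.0, 1.0) if np.any(dose == g)
    }
    T = data.T
    grid = np.arange(1, T + 1)

    chi2_rep = np.empty(len(take))
    chi2_obs = np.empty(len(take))
    for k, di in enumerate(take):
        mean, cov = samples.unpack(pooled[di])
        if hasattr(cov, "G"):  # LMM comparator
            from .mean_model import lmm_marginal_covariance

            def cov_at(t):
                return lmm_marginal_covariance(cov, t)

        else:
            pacf = evaluate_pacf(cov, samples.basis, T)
            sd = np.sqrt(evaluate_variance(cov, grid, basis=samples.basis))

            def cov_at(t):
                s = sd[t - 1]
                S = s[:, None] * corr_for_times(pacf, t) * s[None, :]
                if cov.sigma_b > 0:
                    S = S + cov.sigma_b**2
                return S

        def mean_at(t, dose_i, d_i):
            if isinstance(mean, CLMParams):
                return clm_mean_vector(mean, t, dose_i, d_i)
            return mean.mean_vector(t, dose_i)

        # observed-data discrepancy under this draw's parameters
        obs = 0.0
        for i in range(data.n_subjects):
            t = data.times[i]
            r = data.y[i] - mean_at(t, dose[i], data.dropout[i])
            S = cov_at(t)
            obs += float(r @ cho_solve(cho_factor(S, lower=True), r))
        chi2_obs[k] = obs

        # replicated data under the same parameters
        rep = 0.0
        for i in range(data.n_subjects):
            srng = _subject_rng(k, data.ids[i])
            pool = draw_pool.get(dose[i], data.dropout)
            d_rep = float(srng.choice(pool))
            d_rep_grid = min(T, max(1, int(np.floor(d_rep / data.resolution + 0.5))))
            t = [1]
            while True:
                nxt = t[-1] + int(srng.choice(gaps))
                if nxt > d_rep_grid or nxt > T:
                    break
                t.append(nxt)
            t = np.asarray(t, dtype=int)
            mu = mean_at(t, dose[i], d_rep)
            S = cov_at(t)
            L = np.linalg.cholesky(S)
            y_rep = mu + L @ srng.standard_normal(len(t))
            z = np.linalg.solve(L, y_rep - mu)
            rep += float(z @ z)
        chi2_rep[k] = rep

    return PPCReport(chi2_rep=chi2_rep, chi2_obs=chi2_obs)
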