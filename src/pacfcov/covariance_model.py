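"""Regression models mapping low-dimensional parameters to a banded PACF and
a variance function.

Two families are supported on the Fisher-z scale:

* stationary:      z(pi(t, t+j)) = (gamma0 + gamma1 * j) * 1{j <= a}
* non-stationary:  z(pi(t, t+j)) = (g0(t) + g1(t) * j) * 1{j <= a}

with g0, g1 smooth functions of (scaled) time modeled by penalized low-rank
thin-plate splines.  Monotone decay of the partials in lag is enforced by
gamma1 <= 0 (stationary) or g1(t) <= 0 at every grid point (non-stationary).
The marginal variance is log-linear in scaled time (a spline form is also
available), and a random intercept with standard deviation sigma_b adds a
constant sigma_b^2 to every covariance entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pacf_core import BandedPACF, corr_for_times, inverse_fisher_z

__all__ = [
    "ThinPlateBasis",
    "CovarianceParams",
    "ConstraintViolation",
    "build_thin_plate_basis",
    "evaluate_pacf",
    "evaluate_variance",
    "build_subject_covariance",
]


class ConstraintViolation(ValueError):
    """A parameter vector violates a model shape constraint (e.g. g1(t) > 0).

    Samplers must treat this as a rejected state, never clamp."""


@dataclass
class ThinPlateBasis:
    """Low-rank thin-plate spline basis on a scaled time axis.

    The raw basis at scaled time u = t/s is {1, u, |u - k_1|^3, ..., |u - k_K|^3}
    with scaled knots k = knots/s.  The radial block T2 is reparameterized as
    Z = T2 @ Omega^{-1/2} (symmetric inverse square root of the penalty
    Omega[l, k] = |k_l - k_k|^3) so the spline coefficients can carry
    independent mean-zero Normal priors.
    """

    knots: np.ndarray  # scaled knot locations nu_k / s
    scale: float
    grid_length: int
    fixed_design: np.ndarray  # (T, 2): columns (1, t/s)
    raw_radial: np.ndarray  # (T, K): |t/s - nu_k/s|^3
    penalty: np.ndarray  # (K, K): Omega
    random_design: np.ndarray  # (T, K): raw_radial @ Omega^{-1/2}

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def design_row(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Fixed and random design rows at (possibly off-grid) time t."""
        u = t / self.scale
        fixed = np.array([1.0, u])
        raw = np.abs(u - self.knots) ** 3
        return fixed, raw @ self._omega_inv_sqrt

    # filled by the builder; kept off the dataclass signature
    _omega_inv_sqrt: np.ndarray = field(default=None, repr=False)


def _sym_inv_sqrt(M: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition.

    Eigenvalues are floored at ``floor`` times the largest magnitude to guard
    against numerically singular penalties.
    """
    vals, vecs = np.linalg.eigh(M)
    top = np.max(np.abs(vals))
    if top <= 0:
        raise np.linalg.LinAlgError(
            "penalty matrix is numerically zero; add jitter to the knots"
        )
    vals = np.maximum(np.abs(vals), floor * top)
    return (vecs / np.sqrt(vals)) @ vecs.T


def build_thin_plate_basis(grid_length: int, knots, scale: float) -> ThinPlateBasis:
    """Construct the thin-plate basis for grid times 1..grid_length.

    Parameters
    ----------
    grid_length : int
        T, the number of grid points.
    knots : array_like
        Strictly increasing knot locations in (0, grid_length], on the
        *unscaled* time axis (e.g. 5, 10, ..., 50 for T = 56).
    scale : float
        Time divisor s applied to both grid times and knots (e.g. 50).
    """
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    if np.any(knots <= 0) or np.any(knots > grid_length):
        raise ValueError(f"knots must lie in (0, {grid_length}]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    t = np.arange(1, grid_length + 1, dtype=float) / scale
    k = knots / scale
    fixed = np.column_stack([np.ones_like(t), t])
    raw = np.abs(t[:, None] - k[None, :]) ** 3
    omega = np.abs(k[:, None] - k[None, :]) ** 3
    omega_inv_sqrt = _sym_inv_sqrt(omega)
    basis = ThinPlateBasis(
        knots=k,
        scale=float(scale),
        grid_length=int(grid_length),
        fixed_design=fixed,
        raw_radial=raw,
        penalty=omega,
        random_design=raw @ omega_inv_sqrt,
    )
    basis._omega_inv_sqrt = omega_inv_sqrt
    return basis


def default_knots(grid_length: int, n_knots: int = 10) -> np.ndarray:
    """Equally spaced interior knots, mirroring the 5,10,...,50 layout at T=56."""
    step = grid_length / (n_knots + 1)
    return np.round(step * np.arange(1, n_knots + 1), 6)


@dataclass
class CovarianceParams:
    """Parameters of the covariance model.

    For ``family='stationary'`` the PACF blocks are the scalars
    ``gamma0 = [g0]`` and ``gamma1 = [g1]`` with g1 <= 0.  For
    ``family='nonstationary'`` each block is ``[intercept, slope, xi_1..xi_K]``:
    two fixed-effect coefficients on (1, t/s) followed by K reparameterized
    spline coefficients on the random design.

    ``alpha`` holds the log-variance coefficients — ``[alpha0, alpha1]`` for
    the log-linear form with scaled time t/var_scale, or a full spline block
    for ``variance_form='spline'``.  ``sigma_b`` is the random-intercept SD.
    """

    family: str  # 'stationary' | 'nonstationary'
    a: int
    gamma0: np.ndarray
    gamma1: np.ndarray
    alpha: np.ndarray
    sigma_b: float = 0.0
    sigma_g0: float = 1.0  # smoothing SD for the g0 spline block
    sigma_g1: float = 1.0
    var_scale: float | None = None  # defaults to grid length
    variance_form: str = "loglinear"
    quadratic_lag: bool = False
    gamma2: np.ndarray | None = None  # optional quadratic-lag block

    def __post_init__(self) -> None:
        if self.family not in ("stationary", "nonstationary"):
            raise ValueError(f"unknown family {self.family!r}")
        self.gamma0 = np.atleast_1d(np.asarray(self.gamma0, dtype=float))
        self.gamma1 = np.atleast_1d(np.asarray(self.gamma1, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.gamma2 is not None:
            self.gamma2 = np.atleast_1d(np.asarray(self.gamma2, dtype=float))
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        if self.quadratic_lag and self.gamma2 is None:
            raise ValueError("quadratic_lag=True requires a gamma2 block")
        if self.family == "stationary":
            if self.gamma0.size != 1 or self.gamma1.size != 1:
                raise ValueError("stationary family takes scalar gamma0/gamma1")
            if self.gamma1[0] > 0:
                raise ConstraintViolation("stationary slope gamma1 must be <= 0")


def _pacf_design(params: CovarianceParams, basis: ThinPlateBasis | None, T: int):
    """Evaluate g0(t), g1(t) (and g2(t) if enabled) on the grid 1..T."""
    if params.family == "stationary":
        g0 = np.full(T, params.gamma0[0])
        g1 = np.full(T, params.gamma1[0])
        g2 = np.full(T, params.gamma2[0]) if params.quadratic_lag else None
        return g0, g1, g2
    if basis is None:
        raise ValueError("non-stationary family requires a ThinPlateBasis")
    X = np.hstack([basis.fixed_design, basis.random_design])[:T]

    def _eval(block: np.ndarray) -> np.ndarray:
        if block.size != X.shape[1]:
            raise ValueError(
                f"spline block has {block.size} coefficients, basis expects {X.shape[1]}"
            )
        return X @ block

    g0 = _eval(params.gamma0)
    g1 = _eval(params.gamma1)
    g2 = _eval(params.gamma2) if params.quadratic_lag else None
    return g0, g1, g2


def evaluate_pacf(
    params: CovarianceParams, basis: ThinPlateBasis | None, T: int
) -> BandedPACF:
    """Evaluate the PACF regression model into a :class:`BandedPACF`.

    Raises
    ------
    ConstraintViolation
        If the evaluated lag slope g1(t) is positive at any grid point
        (non-stationary) or gamma1 > 0 (stationary).  Samplers reject such
        proposals; values are never clamped.
    """
    g0, g1, g2 = _pacf_design(params, basis, T)
    if np.any(g1 > 0):
        raise ConstraintViolation(
            "lag slope g1(t) must be <= 0 at every grid point "
            f"(max {np.max(g1):.4g})"
        )
    a = params.a
    table = np.zeros((T, a))
    for j in range(1, a + 1):
        z = g0 + g1 * j
        if g2 is not None:
            z = z + g2 * j**2
        table[:, j - 1] = inverse_fisher_z(z)
    return BandedPACF(T=T, a=a, table=table)


def evaluate_variance(params: CovarianceParams, t, basis: ThinPlateBasis | None = None):
    """Marginal variance sigma^2(t) at grid time(s) t.

    Log-linear form: sigma^2(t) = exp(alpha0 + alpha1 * t / var_scale).
    Spline form: sigma^2(t) = exp(B(t) @ alpha) on the thin-plate basis.
    Strictly positive by construction.
    """
    t = np.asarray(t, dtype=float)
    if params.variance_form == "loglinear":
        if params.alpha.size != 2:
            raise ValueError("loglinear variance takes alpha = (alpha0, alpha1)")
        s = params.var_scale if params.var_scale is not None else (
            basis.grid_length if basis is not None else np.max(t)
        )
        log_var = params.alpha[0] + params.alpha[1] * t / s
    elif params.variance_form == "spline":
        if basis is None:
            raise ValueError("spline variance requires a ThinPlateBasis")
        X = np.hstack([basis.fixed_design, basis.random_design])
        idx = np.asarray(t, dtype=int) - 1
        log_var = X[idx] @ params.alpha
    else:
        raise ValueError(f"unknown variance_form {params.variance_form!r}")
    out = np.exp(log_var)
    return out if out.ndim else float(out)


def build_subject_covariance(
    params: CovarianceParams,
    basis: ThinPlateBasis | None,
    times,
    T: int | None = None,
    pacf: BandedPACF | None = None,
) -> np.ndarray:
    """Marginal covariance at a subject's observation times.

        Sigma_i = sigma_b^2 * J + S_i R_i S_i

    with J the all-ones matrix (random intercept integrated out), S_i the
    diagonal of marginal standard deviations and R_i the serial correlation
    submatrix at ``times``.  Pass a precomputed ``pacf`` to share the cached
    full-grid correlation across subjects.
    """
    times = np.asarray(times, dtype=int)
    if T is None:
        T = int(np.max(times))
    if pacf is None:
        pacf = evaluate_pacf(params, basis, T)
    R = corr_for_times(pacf, times)
    sd = np.sqrt(evaluate_variance(params, times, basis=basis))
    cov = (sd[:, None] * R) * sd[None, :]
    if params.sigma_b > 0:
        cov = cov + params.sigma_b**2
    return cov
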