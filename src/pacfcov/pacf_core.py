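"""Algebra linking banded partial autocorrelation matrices and correlation matrices.

A partial autocorrelation pi(t, t+j) is the correlation between Y(t) and
Y(t+j) conditional on the intervening grid values Y(t+1), ..., Y(t+j-1).  On a
grid 1..T the set of partial autocorrelations forms a T(T-1)/2 hypercube: each
entry varies freely in (-1, 1) and any assignment induces a unique positive
definite correlation matrix.  An *a-banded* PACF sets pi(t, t+j) = 0 for
j > a; the induced correlation matrix then has an a-banded inverse, and all
conversions here invert matrices of dimension at most a (forward map) or
a + 1 (precision construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandedPACF",
    "fisher_z",
    "inverse_fisher_z",
    "pacf_to_corr",
    "corr_to_pacf",
    "banded_precision",
    "corr_for_times",
]

#: values with |pi| >= 1 - _PACF_TOL are rejected rather than clamped
_PACF_TOL = 1e-12


def fisher_z(x):
    """Fisher z-transform, z(x) = arctanh(x) = 0.5*log((1+x)/(1-x)).

    Maps (-1, 1) onto the real line; used as the link function for PACF
    regression models.

    Parameters
    ----------
    x : array_like
        Values strictly inside (-1, 1).

    Returns
    -------
    ndarray or scalar

    Raises
    ------
    ValueError
        If any ``|x| >= 1``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= 1.0):
        raise ValueError("fisher_z requires |x| < 1")
    out = np.arctanh(x)
    return out if out.ndim else float(out)


def inverse_fisher_z(z):
    """Inverse Fisher z-transform, tanh(z); maps the real line into (-1, 1)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


@dataclass
class BandedPACF:
    """Partial autocorrelations pi(t, t+j) on a grid 1..T, zero beyond band a.

    Parameters
    ----------
    T : int
        Grid length (>= 1).
    a : int
        Band width, 0 <= a <= T - 1.  Lags j > a carry pi = 0 implicitly.
    table : ndarray of shape (T, a)
        ``table[t - 1, j - 1]`` holds pi(t, t+j), defined for t + j <= T.
        Entries with t + j > T are ignored (kept at 0).

    Notes
    -----
    Every stored value must lie strictly inside (-1, 1); values within 1e-12
    of the boundary are rejected at construction so near-singular inputs fail
    loudly instead of being truncated.
    """

    T: int
    a: int
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.T = int(self.T)
        self.a = int(self.a)
        if self.T < 1:
            raise ValueError("T must be a positive integer")
        if not 0 <= self.a <= self.T - 1 and not (self.T == 1 and self.a == 0):
            raise ValueError(f"band width a={self.a} outside [0, T-1]=[0, {self.T - 1}]")
        table = np.asarray(self.table, dtype=float)
        if table.shape != (self.T, self.a):
            raise ValueError(
                f"table shape {table.shape} does not match (T, a)=({self.T}, {self.a})"
            )
        # zero out the undefined corner t + j > T, then validate the rest
        for j in range(1, self.a + 1):
            table[self.T - j :, j - 1] = 0.0
        if np.any(np.abs(table) >= 1.0 - _PACF_TOL):
            raise ValueError(
                "partial autocorrelations must satisfy |pi| < 1 - 1e-12; "
                "got max |pi| = %g" % np.max(np.abs(table))
            )
        self.table = table
        self._corr_cache: np.ndarray | None = None

    def pi(self, t: int, j: int) -> float:
        """pi(t, t+j) for 1 <= t < t + j <= T; zero for lags beyond the band."""
        if not (1 <= t < t + j <= self.T):
            raise ValueError(f"(t, j)=({t}, {j}) outside grid 1..{self.T}")
        if j > self.a:
            return 0.0
        return float(self.table[t - 1, j - 1])

    def to_matrix(self) -> np.ndarray:
        """Full T x T partial autocorrelation matrix (unit diagonal)."""
        P = np.eye(self.T)
        for j in range(1, self.a + 1):
            idx = np.arange(self.T - j)
            P[idx, idx + j] = self.table[: self.T - j, j - 1]
            P[idx + j, idx] = self.table[: self.T - j, j - 1]
        return P

    @classmethod
    def from_matrix(cls, P: np.ndarray, a: int) -> "BandedPACF":
        """Build from a full symmetric matrix, reading lags 1..a."""
        P = np.asarray(P, dtype=float)
        T = P.shape[0]
        table = np.zeros((T, a))
        for j in range(1, a + 1):
            idx = np.arange(T - j)
            table[: T - j, j - 1] = P[idx, idx + j]
        return cls(T=T, a=a, table=table)

    @classmethod
    def random(cls, T: int, a: int, rng: np.random.Generator, scale: float = 0.5) -> "BandedPACF":
        """Random draw with entries ~ Uniform(-scale, scale) inside the band."""
        table = rng.uniform(-scale, scale, size=(T, a))
        return cls(T=T, a=a, table=table)

    def _full_corr(self) -> np.ndarray:
        if self._corr_cache is None:
            self._corr_cache = pacf_to_corr(self)
        return self._corr_cache


def _validate_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return R


def pacf_to_corr(p: BandedPACF) -> np.ndarray:
    """Convert a banded PACF to its induced marginal correlation matrix.

    The lag-recursive scheme fills diagonals in order of lag j.  Within the
    band (j <= a) the defining identity is used,

        rho(t, t+j) = r1' S^-1 r3 + pi(t, t+j) * D(t, t+j),

    where S is the correlation matrix of the intervening values, r1 and r3
    the correlation vectors of the endpoints with them, and D the product of
    the two partial standard deviations.  Beyond the band the zero partials
    make the process Markov of order a, so each new entry is a linear
    combination of the previous a entries with coefficients from an
    a-dimensional regression; no inversion ever exceeds dimension a.

    Returns
    -------
    ndarray of shape (T, T)
        Symmetric positive definite correlation matrix.
    """
    T, a = p.T, p.a
    R = np.eye(T)
    if T == 1 or a == 0:
        return R

    # lag 1: rho == pi
    idx = np.arange(T - 1)
    R[idx, idx + 1] = p.table[: T - 1, 0]
    R[idx + 1, idx] = p.table[: T - 1, 0]

    # lags 2..a: full conditioning set of dimension j-1 <= a-1
    for j in range(2, min(a, T - 1) + 1):
        for t in range(T - j):  # 0-based left endpoint
            mid = slice(t + 1, t + j)
            S = R[mid, mid]
            r1 = R[t, mid]
            r3 = R[t + j, mid]
            sol = np.linalg.solve(S, np.column_stack([r1, r3]))
            q11 = float(r1 @ sol[:, 0])
            q33 = float(r3 @ sol[:, 1])
            q13 = float(r1 @ sol[:, 1])
            D = np.sqrt(max(1.0 - q11, 0.0) * max(1.0 - q33, 0.0))
            val = q13 + p.table[t, j - 1] * D
            R[t, t + j] = val
            R[t + j, t] = val

    if a >= T - 1:
        return R

    # regression of Y(s) on its a immediate predecessors, one per right
    # endpoint s; only lags <= a are referenced so all inputs exist already
    starts = np.arange(T - a)  # window start for s = a .. T-1 (0-based)
    win = starts[:, None] + np.arange(a)[None, :]
    W = R[win[:, :, None], win[:, None, :]]  # (T-a, a, a)
    r = R[win, np.arange(a, T)[:, None]]  # (T-a, a)
    B = np.linalg.solve(W, r[..., None])[..., 0]  # (T-a, a)

    # lags beyond the band: rho(t, t+j) = sum_k B[t+j, k] rho(t, t+j-a+k)
    for j in range(a + 1, T):
        s = np.arange(j, T)  # 0-based right endpoints
        t = s - j
        acc = np.zeros(len(s))
        for k in range(a):
            acc += B[s - a, k] * R[t, s - a + k]
        R[t, s] = acc
        R[s, t] = acc
    return R


def corr_to_pacf(R: np.ndarray, a: int) -> BandedPACF:
    """Extract partial autocorrelations up to lag ``a`` from a correlation matrix.

    Inverse of :func:`pacf_to_corr` on banded inputs: for any valid
    BandedPACF ``p``, ``corr_to_pacf(pacf_to_corr(p), p.a)`` reproduces ``p``
    to ~1e-10.

    Raises
    ------
    numpy.linalg.LinAlgError
        If ``R`` is not positive definite; the message names the first
        non-positive-definite leading minor.
    """
    R = _validate_corr(R)
    T = R.shape[0]
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        # locate the offending leading principal minor for the error message
        for k in range(1, T + 1):
            if np.linalg.eigvalsh(R[:k, :k])[0] <= 0:
                raise np.linalg.LinAlgError(
                    f"correlation matrix is not positive definite: leading "
                    f"minor of order {k} is not positive"
                ) from None
        raise
    table = np.zeros((T, a))
    if a >= 1 and T >= 2:
        idx = np.arange(T - 1)
        table[: T - 1, 0] = R[idx, idx + 1]
    for j in range(2, min(a, T - 1) + 1):
        for t in range(T - j):
            mid = slice(t + 1, t + j)
            S = R[mid, mid]
            r1 = R[t, mid]
            r3 = R[t + j, mid]
            sol = np.linalg.solve(S, np.column_stack([r1, r3]))
            q11 = float(r1 @ sol[:, 0])
            q33 = float(r3 @ sol[:, 1])
            q13 = float(r1 @ sol[:, 1])
            D = np.sqrt(max(1.0 - q11, 1e-300) * max(1.0 - q33, 1e-300))
            table[t, j - 1] = (R[t, t + j] - q13) / D
    return BandedPACF(T=T, a=a, table=table)


def banded_precision(p: BandedPACF) -> tuple[np.ndarray, float]:
    """Precision matrix and log-determinant of the correlation induced by ``p``.

    Because the a-banded PACF makes the process Markov of order a, the
    precision factorizes over the cliques {t, ..., t+a} of the band graph with
    separators {t+1, ..., t+a}:

        R^-1 = sum_c pad(inv(R_c)) - sum_s pad(inv(R_s))
        log|R| = sum_c log|R_c| - sum_s log|R_s|

    Only (a+1)-dimensional matrices are inverted, and entries outside the
    band are exact zeros by construction (never touched).

    Returns
    -------
    (precision, logdet) : (ndarray, float)
        ``precision`` is the inverse of ``pacf_to_corr(p)``; ``logdet`` is
        log|R| (of the correlation matrix, not its inverse).
    """
    T, a = p.T, p.a
    if a == 0 or T == 1:
        return np.eye(T), 0.0
    R = p._full_corr()
    if T <= a + 1:
        sign, logdet = np.linalg.slogdet(R)
        return np.linalg.inv(R), float(logdet)

    w = a + 1
    P = np.zeros((T, T))
    starts = np.arange(T - a)  # clique windows [t, t+a]
    cw = starts[:, None] + np.arange(w)[None, :]
    cliques = R[cw[:, :, None], cw[:, None, :]]
    inv_c = np.linalg.inv(cliques)
    _, logdet_c = np.linalg.slogdet(cliques)
    for i, t in enumerate(starts):
        P[t : t + w, t : t + w] += inv_c[i]

    sep_starts = np.arange(1, T - a)  # separators [t+1, t+a]
    sw = sep_starts[:, None] + np.arange(a)[None, :]
    seps = R[sw[:, :, None], sw[:, None, :]]
    inv_s = np.linalg.inv(seps)
    _, logdet_s = np.linalg.slogdet(seps)
    for i, t in enumerate(sep_starts):
        P[t : t + a, t : t + a] -= inv_s[i]

    return P, float(np.sum(logdet_c) - np.sum(logdet_s))


def corr_for_times(p: BandedPACF, times) -> np.ndarray:
    """Correlation submatrix at a subject's observation times.

    ``times`` are strictly increasing 1-based grid indices.  The full-grid
    correlation matrix is computed once per BandedPACF and cached, so
    repeated subject-level calls are cheap.
    """
    times = np.asarray(times, dtype=int)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-d index array")
    if np.any(times < 1) or np.any(times > p.T):
        raise ValueError(f"times must lie in 1..{p.T}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    R = p._full_corr()
    idx = times - 1
    return R[np.ix_(idx, idx)]
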