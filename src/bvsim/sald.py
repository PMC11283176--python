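"""Multivariate shifted asymmetric Laplace distribution (SALD).

The d-dimensional SALD(mu, Sigma, gamma) is the normal variance-mean mixture

    Y = mu + V * gamma + sqrt(V) * Z,    V ~ Exp(1),  Z ~ N_d(0, Sigma),

whose density involves the modified Bessel function of the third kind
K_nu with nu = (2 - d) / 2.  Conditionally on an observation y, the mixing
variable V follows a generalized inverse Gaussian (GIG) law whose first and
inverse moments are ratios of Bessel functions; those moments drive the
E-step of the ECM estimator.

All Bessel evaluations are carried out in log scale so that ratios
K_{nu+1}/K_nu never overflow, even for the large negative integer orders
(nu = 1 - m) produced by clusters with many members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "SALDParams",
    "GIGConditional",
    "log_bessel_k",
    "bessel_k_ratio",
    "sald_logpdf",
    "sald_sample",
    "sald_moments",
    "gig_conditional_moments",
]

# Quadratic forms below this floor are treated as "observation at the
# location"; the GIG moments are then evaluated at the floor, which
# reproduces the small-argument limits without special-casing.
B_FLOOR = 1e-10

# Scatter matrices with condition number above this are rejected.
MAX_CONDITION = 1e12


@dataclass
class SALDParams:
    """Parameters of a d-dimensional SALD: location, scatter, skewness."""

    mu: np.ndarray
    Sigma: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        d = self.mu.shape[0]
        if self.gamma.shape != (d,) or self.Sigma.shape != (d, d):
            raise ValueError(
                f"dimension mismatch: mu {self.mu.shape}, gamma "
                f"{self.gamma.shape}, Sigma {self.Sigma.shape}"
            )
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        eigvals = np.linalg.eigvalsh(self.Sigma)
        if eigvals[0] <= 0:
            raise ValueError("Sigma must be positive definite")
        if eigvals[-1] / eigvals[0] > MAX_CONDITION:
            raise ValueError(
                f"Sigma condition number {eigvals[-1] / eigvals[0]:.3g} "
                f"exceeds {MAX_CONDITION:.0e}"
            )

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    @property
    def nu(self) -> float:
        """Bessel order (2 - d) / 2 appearing in the density."""
        return (2.0 - self.d) / 2.0


@dataclass
class GIGConditional:
    """Conditional moments of the mixing variable V given an observation.

    ``a`` is 2 + gamma' Sigma^{-1} gamma, ``b`` the Mahalanobis quadratic
    form delta(y, mu, Sigma), ``nu`` the Bessel order; ``ev`` and ``evinv``
    are E[V | y] and E[1/V | y].
    """

    a: float
    b: float
    nu: float
    ev: float = field(default=np.nan)
    evinv: float = field(default=np.nan)


def log_bessel_k(nu: float, x) -> np.ndarray | float:
    """log K_nu(x), stable for |nu| <= ~200 and x in (1e-12, 1e6).

    K is symmetric in the order, so only |nu| matters.  The value at the
    fractional part of |nu| (and at +1) comes from the exponentially scaled
    ``scipy.special.kve``; integer steps use the three-term recurrence
    K_{o+1}(x) = K_{o-1}(x) + (2 o / x) K_o(x) evaluated in log space with
    ``logaddexp`` (all terms positive), which cannot overflow.

    ``x`` may be a scalar or an array; ``nu`` must be a scalar.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("log_bessel_k requires x > 0")
    anu = abs(float(nu))
    frac = anu - np.floor(anu)
    nsteps = int(np.floor(anu))
    with np.errstate(divide="ignore"):
        lk_lo = np.log(special.kve(frac, x)) - x
        if nsteps == 0:
            return lk_lo if lk_lo.ndim else float(lk_lo)
        lk_hi = np.log(special.kve(frac + 1.0, x)) - x
    for j in range(1, nsteps):
        order = frac + j
        lk_lo, lk_hi = lk_hi, np.logaddexp(lk_lo, np.log(2.0 * order / x) + lk_hi)
    return lk_hi if lk_hi.ndim else float(lk_hi)


def log_bessel_k_pair(nu: float, x) -> tuple[np.ndarray, np.ndarray]:
    """(log K_nu(x), log K_{nu+1}(x)) sharing one recurrence pass.

    For the model's orders nu = 1 - m the two magnitudes |nu| and |nu + 1|
    are adjacent integers, so both values fall out of the same upward
    recurrence; otherwise the second order is computed separately.
    """
    anu, anu1 = abs(float(nu)), abs(float(nu) + 1.0)
    if abs(anu - anu1) == 1.0:
        lo, hi = sorted((anu, anu1))
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0.0):
            raise ValueError("log_bessel_k_pair requires x > 0")
        frac = lo - np.floor(lo)
        nsteps = int(np.floor(lo))
        with np.errstate(divide="ignore"):
            lk_lo = np.log(special.kve(frac, x)) - x
            lk_hi = np.log(special.kve(frac + 1.0, x)) - x
        for j in range(1, nsteps + 1):
            order = frac + j
            lk_lo, lk_hi = lk_hi, np.logaddexp(lk_lo, np.log(2.0 * order / x) + lk_hi)
        pair = {lo: lk_lo, hi: lk_hi}
        return pair[anu], pair[anu1]
    return log_bessel_k(nu, x), log_bessel_k(nu + 1.0, x)


def bessel_k_ratio(nu: float, x) -> np.ndarray | float:
    """R_nu(x) = K_{nu+1}(x) / K_nu(x), computed from log Bessel values."""
    lk, lk1 = log_bessel_k_pair(nu, x)
    return np.exp(lk1 - lk)


def _chol_pieces(params: SALDParams):
    L = np.linalg.cholesky(params.Sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return L, logdet


def sald_logpdf(y, params: SALDParams) -> float:
    """Log density of the d-dimensional SALD at a single point y.

    Uses log-scale Bessel evaluation throughout; when y is numerically at
    the location mu, the quadratic form is floored at ``B_FLOOR`` (the
    density diverges there for d >= 3, exactly as the limiting form does).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.shape != params.mu.shape:
        raise ValueError("y has wrong dimension")
    L, logdet = _chol_pieces(params)
    resid = y - params.mu
    # solves against the Cholesky factor: Sigma^{-1} v = L^{-T} L^{-1} v
    sr = np.linalg.solve(L, resid)
    sg = np.linalg.solve(L, params.gamma)
    delta = max(float(sr @ sr), B_FLOOR)
    gsg = float(sg @ sg)
    cross = float(sr @ sg)
    a = 2.0 + gsg
    nu = params.nu
    u = np.sqrt(a * delta)
    return (
        np.log(2.0)
        + cross
        - 0.5 * params.d * np.log(2.0 * np.pi)
        - 0.5 * logdet
        + 0.5 * nu * (np.log(delta) - np.log(a))
        + log_bessel_k(nu, u)
    )


def sald_sample(params: SALDParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows from the SALD via its normal variance-mean mixture form."""
    if n < 1:
        raise ValueError("n must be >= 1")
    v = rng.exponential(scale=1.0, size=n)
    L, _ = _chol_pieces(params)
    z = rng.standard_normal((n, params.d)) @ L.T
    return params.mu + v[:, None] * params.gamma + np.sqrt(v)[:, None] * z


def sald_moments(params: SALDParams) -> tuple[np.ndarray, np.ndarray]:
    """Mean mu + gamma and covariance Sigma + gamma gamma' of the SALD."""
    mean = params.mu + params.gamma
    cov = params.Sigma + np.outer(params.gamma, params.gamma)
    return mean, cov


def gig_conditional_moments(a, b, nu: float) -> GIGConditional:
    """E[V | y] and E[1/V | y] for the GIG conditional of the mixing variable.

    With u = sqrt(a b) and R_nu(u) = K_{nu+1}(u) / K_nu(u):

        E[V | y]   = sqrt(b / a) * R_nu(u)
        E[1/V | y] = sqrt(a / b) * R_nu(u) - 2 nu / b

    ``a`` and ``b`` may be scalars or equal-shaped arrays (``nu`` scalar);
    a scalar call returns a populated :class:`GIGConditional`.  ``b`` is
    floored at ``B_FLOOR``, which realises the small-argument limit of the
    moments for observations at the location.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.maximum(np.asarray(b, dtype=float), B_FLOOR)
    if np.any(a_arr <= 0.0):
        raise ValueError("gig_conditional_moments requires a > 0")
    u = np.sqrt(a_arr * b_arr)
    ratio = bessel_k_ratio(nu, u)
    ev = np.sqrt(b_arr / a_arr) * ratio
    evinv = np.sqrt(a_arr / b_arr) * ratio - 2.0 * nu / b_arr
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return GIGConditional(
            a=float(a_arr), b=float(b_arr), nu=float(nu),
            ev=float(ev), evinv=float(evinv),
        )
    res = GIGConditional(a=a_arr, b=b_arr, nu=float(nu))
    res.ev, res.evinv = ev, evinv
    return res
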