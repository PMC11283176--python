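"""Data containers, identifiability parametrization, and marginal likelihood.

The bivariate single-index mixed model (BV-SIM) observes, for member j of
subject i, a response pair

    y_ij = ( g1(x_ij1' beta1) + z_ij1' b_i1 ,
             g2(x_ij2' beta2) + z_ij2' b_i2 )  + eps_ij,

with subject random effects b_i = (b_i1, b_i2) ~ SAL(0, Omega, 0) and errors
eps_ij ~ SAL2(0, Sigma, gamma), sharing one exponential mixing variable V_i
per subject.  Marginally each stacked subject vector y_i is a 2 m_i
dimensional SALD with location mu_i, scatter G_i = Z_i' Omega Z_i + I (x)
Sigma and skewness 1_{m_i} (x) gamma.

The index coefficient vectors are identified by unit norm and a positive
first component; the "delete one component" map and its Jacobian remove the
norm constraint from optimization.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sald import B_FLOOR, log_bessel_k

__all__ = [
    "ClusteredBivariateData",
    "BVSIMParams",
    "full_beta",
    "compute_mu",
    "marginal_loglik",
    "subject_scatter",
    "read_long_csv",
    "write_long_csv",
]


# ---------------------------------------------------------------------------
# data container


@dataclass
class ClusteredBivariateData:
    """Long-format clustered bivariate data.

    ``z1``/``z2`` include the leading intercept column of ones.  Rows are
    grouped by subject; ``row_subject`` maps each row to its subject index
    and ``offsets`` gives the first row of each subject (for reduceat).
    """

    subject_ids: np.ndarray
    cluster_sizes: np.ndarray
    y: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    row_subject: np.ndarray = field(init=False)
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)
        for name in ("y", "x1", "x2", "z1", "z2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.subject_ids)
        if len(self.cluster_sizes) != n:
            raise ValueError("subject_ids and cluster_sizes disagree")
        if np.any(self.cluster_sizes < 1):
            raise ValueError("all cluster sizes must be >= 1")
        N = int(self.cluster_sizes.sum())
        for name in ("y", "x1", "x2", "z1", "z2"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[0] != N:
                raise ValueError(f"{name} must have {N} rows")
        if self.y.shape[1] != 2:
            raise ValueError("y must have two columns")
        for name in ("z1", "z2"):
            if not np.allclose(getattr(self, name)[:, 0], 1.0):
                raise ValueError(f"{name} must start with an intercept column of ones")
        if np.isnan(self.y).any() or np.isnan(self.x1).any() or np.isnan(self.x2).any():
            raise ValueError("missing values are not supported (complete cases only)")
        self.offsets = np.concatenate([[0], np.cumsum(self.cluster_sizes)[:-1]])
        self.row_subject = np.repeat(np.arange(n), self.cluster_sizes)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> tuple[int, int]:
        return self.x1.shape[1], self.x2.shape[1]

    @property
    def q(self) -> tuple[int, int]:
        """Number of random-effect covariates per response (excl. intercept)."""
        return self.z1.shape[1] - 1, self.z2.shape[1] - 1

    def subject_rows(self, i: int) -> slice:
        start = self.offsets[i]
        return slice(start, start + self.cluster_sizes[i])

    def subset_subjects(self, idx) -> "ClusteredBivariateData":
        """New dataset from (possibly repeated) subject indices.

        Repeated subjects get fresh labels, as needed by the cluster
        bootstrap.
        """
        idx = np.asarray(idx, dtype=int)
        rows = np.concatenate([np.arange(self.offsets[i], self.offsets[i] + self.cluster_sizes[i]) for i in idx])
        return ClusteredBivariateData(
            subject_ids=np.arange(len(idx)),
            cluster_sizes=self.cluster_sizes[idx],
            y=self.y[rows],
            x1=self.x1[rows],
            x2=self.x2[rows],
            z1=self.z1[rows],
            z2=self.z2[rows],
        )


# ---------------------------------------------------------------------------
# parameters


def _check_pd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(mat)[0] <= 0:
        raise ValueError(f"{name} must be positive definite")


@dataclass
class BVSIMParams:
    """Model parameters under the unit-norm, positive-first-entry convention.

    ``validate=False`` skips the invariant checks (used in the estimation
    hot loop, where every update maintains them by construction).
    """

    beta1: np.ndarray
    beta2: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    gamma: np.ndarray
    Sigma: np.ndarray
    Omega: np.ndarray
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        for name in ("beta1", "beta2", "theta1", "theta2", "gamma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.Omega = np.asarray(self.Omega, dtype=float)
        if not validate:
            return
        for b, name in ((self.beta1, "beta1"), (self.beta2, "beta2")):
            if abs(np.linalg.norm(b) - 1.0) > 1e-8:
                raise ValueError(f"{name} must have unit norm")
            if b[0] <= 0:
                raise ValueError(f"{name} must have a positive first component")
        if self.gamma.shape != (2,):
            raise ValueError("gamma must be a 2-vector")
        if self.Sigma.shape != (2, 2):
            raise ValueError("Sigma must be 2x2")
        _check_pd(self.Sigma, "Sigma")
        _check_pd(self.Omega, "Omega")

    def flatten(self) -> np.ndarray:
        """All scalar parameters as one vector (for convergence checks)."""
        iu2 = np.triu_indices(2)
        iuo = np.triu_indices(self.Omega.shape[0])
        return np.concatenate([
            self.beta1, self.beta2, self.theta1, self.theta2, self.gamma,
            self.Sigma[iu2], self.Omega[iuo],
        ])

    def copy(self) -> "BVSIMParams":
        return BVSIMParams(
            beta1=self.beta1.copy(), beta2=self.beta2.copy(),
            theta1=self.theta1.copy(), theta2=self.theta2.copy(),
            gamma=self.gamma.copy(), Sigma=self.Sigma.copy(),
            Omega=self.Omega.copy(),
        )


def full_beta(beta_minus1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Delete-one-component map: beta and its p x (p-1) Jacobian.

    beta = (sqrt(1 - ||b||^2), b) for b = beta_minus1 inside the unit ball;
    the Jacobian has first row -b' / sqrt(1 - ||b||^2) above an identity.
    """
    b = np.asarray(beta_minus1, dtype=float).ravel()
    nrm2 = float(b @ b)
    if nrm2 >= 1.0:
        raise ValueError("beta_minus1 must lie strictly inside the unit ball")
    first = np.sqrt(1.0 - nrm2)
    beta = np.concatenate([[first], b])
    jac = np.vstack([-b / first, np.eye(len(b))])
    return beta, jac


# ---------------------------------------------------------------------------
# mean structure


def compute_mu(
    params: BVSIMParams,
    data: ClusteredBivariateData,
    basis1,
    basis2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-effect means mu_ij and the two spline design blocks.

    Returns ``(mu, B1, B2)`` with ``mu`` of shape (N, 2) and ``Bk`` the
    normalized design of index k evaluated at the current index values
    (the per-member blocks of the stacked W_i design).
    """
    from .splines import bspline_design

    u1 = data.x1 @ params.beta1
    u2 = data.x2 @ params.beta2
    B1 = bspline_design(u1, basis1)
    B2 = bspline_design(u2, basis2)
    mu = np.column_stack([B1 @ params.theta1, B2 @ params.theta2])
    return mu, B1, B2


def subject_scatter(params: BVSIMParams, data: ClusteredBivariateData, i: int) -> np.ndarray:
    """Explicit 2 m_i x 2 m_i scatter G_i = Z_i' Omega Z_i + I (x) Sigma."""
    rows = data.subject_rows(i)
    z1, z2 = data.z1[rows], data.z2[rows]
    m = z1.shape[0]
    q1p, q2p = z1.shape[1], z2.shape[1]
    Zi = np.zeros((q1p + q2p, 2 * m))
    for j in range(m):
        Zi[:q1p, 2 * j] = z1[j]
        Zi[q1p:, 2 * j + 1] = z2[j]
    return Zi.T @ params.Omega @ Zi + np.kron(np.eye(m), params.Sigma)


# ---------------------------------------------------------------------------
# marginal likelihood machinery (shared with the E-step)


class SubjectStats:
    """Per-subject Woodbury pieces of the marginal SALD likelihood.

    For each subject, with Lambda_i = I (x) Sigma and D = q1 + q2 + 2:

      - ``A``       (n, D, D): Z_i Lambda^{-1} Z_i'
      - ``Delta``   (n, D, D): (Omega^{-1} + A)^{-1}
      - ``u``       (n, D):    Z_i Lambda^{-1} (y_i - mu_i)
      - ``w``       (n, D):    Z_i Lambda^{-1} gamma*_i
      - ``a``, ``b`` (n,):     2 + gamma*' G^{-1} gamma*, resid' G^{-1} resid
      - ``cross``   (n,):      resid' G^{-1} gamma*
      - ``logdetG`` (n,)
    """

    def __init__(self, params: BVSIMParams, data: ClusteredBivariateData, mu: np.ndarray):
        z1, z2 = data.z1, data.z2
        q1p, q2p = z1.shape[1], z2.shape[1]
        D = q1p + q2p
        n = data.n_subjects
        off = data.offsets
        m = data.cluster_sizes

        Sigma_inv = np.linalg.inv(params.Sigma)
        s11, s12, s22 = Sigma_inv[0, 0], Sigma_inv[0, 1], Sigma_inv[1, 1]
        sign, logdet_Sigma = np.linalg.slogdet(params.Sigma)

        resid = data.y - mu                       # (N, 2)
        t = resid @ Sigma_inv                     # Sigma^{-1} resid rows
        tg = params.gamma @ Sigma_inv             # (2,)

        # per-subject sums of outer products of z blocks (data-only; cached)
        zc = getattr(data, "_zblock_cache", None)
        if zc is None:
            zc = (
                np.add.reduceat(z1[:, :, None] * z1[:, None, :], off, axis=0),
                np.add.reduceat(z1[:, :, None] * z2[:, None, :], off, axis=0),
                np.add.reduceat(z2[:, :, None] * z2[:, None, :], off, axis=0),
                np.add.reduceat(z1, off, axis=0),
                np.add.reduceat(z2, off, axis=0),
            )
            object.__setattr__(data, "_zblock_cache", zc)
        S11, S12, S22, sz1_c, sz2_c = zc
        A = np.zeros((n, D, D))
        A[:, :q1p, :q1p] = s11 * S11
        A[:, :q1p, q1p:] = s12 * S12
        A[:, q1p:, :q1p] = s12 * np.swapaxes(S12, 1, 2)
        A[:, q1p:, q1p:] = s22 * S22

        u = np.concatenate([
            np.add.reduceat(z1 * t[:, [0]], off, axis=0),
            np.add.reduceat(z2 * t[:, [1]], off, axis=0),
        ], axis=1)                                # (n, D)
        sz1, sz2 = sz1_c, sz2_c
        w = np.concatenate([tg[0] * sz1, tg[1] * sz2], axis=1)

        Omega_inv = np.linalg.inv(params.Omega)
        core = Omega_inv[None, :, :] + A
        self.Delta = np.linalg.inv(core)
        sign_o, logdet_Omega = np.linalg.slogdet(params.Omega)
        sign_c, logdet_core = np.linalg.slogdet(core)
        if sign <= 0 or sign_o <= 0 or np.any(sign_c <= 0):
            raise np.linalg.LinAlgError("G_i is not positive definite (check Sigma/Omega)")

        rLr = np.add.reduceat(np.einsum("nk,nk->n", resid, t), off)
        rLg = np.add.reduceat(t @ params.gamma, off)
        gLg = m * float(params.gamma @ tg)

        uDu = np.einsum("nd,nde,ne->n", u, self.Delta, u)
        wDw = np.einsum("nd,nde,ne->n", w, self.Delta, w)
        uDw = np.einsum("nd,nde,ne->n", u, self.Delta, w)

        self.A, self.u, self.w = A, u, w
        self.b = rLr - uDu
        self.a = 2.0 + gLg - wDw
        self.cross = rLg - uDw
        self.logdetG = m * logdet_Sigma + logdet_Omega + logdet_core
        self.resid, self.t = resid, t
        self.Sigma_inv, self.Omega_inv = Sigma_inv, Omega_inv
        self.S11, self.S12, self.S22 = S11, S12, S22
        self.sz1, self.sz2 = sz1, sz2
        self.m = m

    def loglik(self) -> float:
        """Sum of per-subject marginal SALD log densities."""
        m = self.m
        b = np.maximum(self.b, B_FLOOR)
        total = 0.0
        for mi in np.unique(m):
            sel = m == mi
            nu = 1.0 - mi
            uval = np.sqrt(self.a[sel] * b[sel])
            total += float(np.sum(
                np.log(2.0)
                + self.cross[sel]
                - mi * np.log(2.0 * np.pi)
                - 0.5 * self.logdetG[sel]
                + 0.5 * nu * (np.log(b[sel]) - np.log(self.a[sel]))
                + log_bessel_k(nu, uval)
            ))
        return total


def marginal_loglik(
    params: BVSIMParams,
    data: ClusteredBivariateData,
    basis1,
    basis2,
) -> float:
    """Marginal log-likelihood: sum over subjects of the 2m_i-dim SALD logpdf."""
    mu, _, _ = compute_mu(params, data, basis1, basis2)
    return SubjectStats(params, data, mu).loglik()


# ---------------------------------------------------------------------------
# long-format text IO


def write_long_csv(data: ClusteredBivariateData, path: str | Path) -> None:
    """Write the long-format table (intercept columns are not stored)."""
    p1, p2 = data.p
    q1, q2 = data.q
    cols: dict[str, np.ndarray] = {
        "subject": np.asarray(data.subject_ids)[data.row_subject],
        "y1": data.y[:, 0],
        "y2": data.y[:, 1],
    }
    for k in range(p1):
        cols[f"x1_{k + 1}"] = data.x1[:, k]
    for k in range(p2):
        cols[f"x2_{k + 1}"] = data.x2[:, k]
    for k in range(q1):
        cols[f"z1_{k + 1}"] = data.z1[:, k + 1]
    for k in range(q2):
        cols[f"z2_{k + 1}"] = data.z2[:, k + 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_long_csv(path: str | Path) -> ClusteredBivariateData:
    """Read the long-format table; intercepts are added internally."""
    df = pd.read_csv(path)
    required = {"subject", "y1", "y2"}
    if not required.issubset(df.columns):
        missing = required - set(df.columns)
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0])
        raise ValueError(f"missing values are not supported (first offending row: {bad})")

    def block(prefix: str) -> np.ndarray:
        names = sorted(
            (c for c in df.columns if c.startswith(prefix)),
            key=lambda c: int(c.split("_")[1]),
        )
        if not names:
            raise ValueError(f"no columns with prefix {prefix!r}")
        return df[names].to_numpy(dtype=float)

    # keep rows grouped by subject in order of first appearance
    subj_col = df["subject"].to_numpy()
    ids, first = np.unique(subj_col, return_index=True)
    ids = ids[np.argsort(first)]
    order = np.concatenate([np.flatnonzero(subj_col == s) for s in ids])
    df = df.iloc[order].reset_index(drop=True)
    subj_col = df["subject"].to_numpy()
    sizes = np.array([(subj_col == s).sum() for s in ids])

    N = len(df)
    ones = np.ones((N, 1))
    z1_cols = [c for c in df.columns if c.startswith("z1_")]
    z2_cols = [c for c in df.columns if c.startswith("z2_")]
    z1 = np.hstack([ones, block("z1_")]) if z1_cols else ones.copy()
    z2 = np.hstack([ones, block("z2_")]) if z2_cols else ones.copy()
    return ClusteredBivariateData(
        subject_ids=ids,
        cluster_sizes=sizes,
        y=df[["y1", "y2"]].to_numpy(dtype=float),
        x1=block("x1_"),
        x2=block("x2_"),
        z1=z1,
        z2=z2,
    )
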