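"""Normalized B-spline bases for the index functions.

Bases are the standard Cox-de Boor B-splines over a clamped knot vector,
rescaled by the basis dimension K so that the basis values at any point sum
to K (a convenient normalization that leaves the spanned spline space
unchanged).  The interior-knot count is chosen by a Schwarz information
criterion over an integer grid centred on n^{1/(2s+1)}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasisSpec",
    "make_basis_spec",
    "bspline_design",
    "bspline_deriv_design",
    "sic_knot_grid",
    "select_knots_sic",
]

logger = logging.getLogger(__name__)

# keep clamped evaluation strictly inside the support
_EDGE_EPS = 1e-10


@dataclass(frozen=True)
class SplineBasisSpec:
    """A clamped B-spline basis: order, full knot vector, basis dimension.

    ``knots`` is the full vector with boundary knots replicated to
    multiplicity ``order``; ``n_interior`` interior knots lie strictly
    inside the support, and ``n_basis = n_interior + order``.
    """

    order: int
    knots: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "knots", np.asarray(self.knots, dtype=float))
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be nondecreasing")
        if len(self.knots) < 2 * self.order:
            raise ValueError("knot vector too short for the requested order")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.knots[self.order - 1]), float(self.knots[-self.order])

    @property
    def n_interior(self) -> int:
        return len(self.knots) - 2 * self.order

    @property
    def n_basis(self) -> int:
        return self.n_interior + self.order


def make_basis_spec(
    u: np.ndarray,
    n_interior: int,
    order: int = 4,
    support: tuple[float, float] | None = None,
) -> SplineBasisSpec:
    """Build a clamped basis with interior knots at equally spaced quantiles.

    The support defaults to the observed range of ``u``.  Quantile knots are
    robust to skewed index distributions; coincident quantiles are nudged
    apart to keep the knot sequence strictly increasing inside the support.
    """
    u = np.asarray(u, dtype=float)
    a, b = (float(u.min()), float(u.max())) if support is None else support
    if not b > a:
        raise ValueError("degenerate support: all index values equal")
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(u, probs)
        interior = np.clip(interior, a + _EDGE_EPS, b - _EDGE_EPS)
        # enforce strict monotonicity for stability of the basis
        span = (b - a) * 1e-8
        for k in range(1, n_interior):
            if interior[k] <= interior[k - 1]:
                interior[k] = interior[k - 1] + span
        interior = np.clip(interior, a + _EDGE_EPS, b - _EDGE_EPS)
    else:
        interior = np.empty(0)
    knots = np.concatenate([np.full(order, a), interior, np.full(order, b)])
    return SplineBasisSpec(order=order, knots=knots)


def _clamp(u: np.ndarray, spec: SplineBasisSpec) -> np.ndarray:
    a, b = spec.support
    width = b - a
    return np.clip(u, a, b - _EDGE_EPS * max(1.0, abs(width)))


def bspline_design(u, spec: SplineBasisSpec) -> np.ndarray:
    """n x K design of K-normalized basis values; rows sum to K.

    Values outside the support are clamped to the boundary.
    """
    u = _clamp(np.atleast_1d(np.asarray(u, dtype=float)), spec)
    degree = spec.order - 1
    design = BSpline.design_matrix(u, spec.knots, degree).toarray()
    return spec.n_basis * design


def bspline_deriv_design(u, spec: SplineBasisSpec) -> np.ndarray:
    """Entrywise derivative of :func:`bspline_design` (same K-scaling).

    Uses the exact lower-order identity
    B'_{k,o}(u) = (o-1) [ B_{k,o-1}(u)/(t_{k+o-1}-t_k)
                        - B_{k+1,o-1}(u)/(t_{k+o}-t_{k+1}) ].
    """
    u = _clamp(np.atleast_1d(np.asarray(u, dtype=float)), spec)
    order, t, K = spec.order, spec.knots, spec.n_basis
    if order == 1:
        return np.zeros((u.shape[0], K))
    degree = order - 1
    lower = BSpline.design_matrix(u, t, degree - 1).toarray()
    # design_matrix at degree-1 over the same knots yields K+1 columns
    ks = np.arange(K)
    d1 = t[ks + order - 1] - t[ks]
    d2 = t[ks + order] - t[ks + 1]
    c1 = np.where(d1 > 0, degree / np.where(d1 > 0, d1, 1.0), 0.0)
    c2 = np.where(d2 > 0, degree / np.where(d2 > 0, d2, 1.0), 0.0)
    out = lower[:, :K] * c1 - lower[:, 1:K + 1] * c2
    return K * out


def sic_knot_grid(n: int, s: int = 2) -> list[int]:
    """Integer grid of interior-knot counts around n^{1/(2s+1)}.

    The grid runs from ceil(0.5 * N_s) to floor(min(5 * N_s, sqrt(n))) with
    N_s = n^{1/(2s+1)}.
    """
    ns = n ** (1.0 / (2 * s + 1))
    lo = int(np.ceil(0.5 * ns))
    hi = int(np.floor(min(5.0 * ns, np.sqrt(n))))
    return list(range(max(lo, 1), hi + 1))


def select_knots_sic(
    n_subjects: int,
    fitter: Callable[[int], tuple[object, float]],
    s: int = 2,
    grid: Sequence[int] | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick the interior-knot count K minimizing SIC(K) = -loglik + log(n) 2K.

    ``fitter`` maps a candidate K to ``(fitted_model, marginal_loglik)``;
    both index functions share the selected K.  Returns the winning K and
    the SIC value per candidate.  Ties go to the smaller K (the penalty is
    strictly increasing).  An empty grid falls back to K = 1 with a warning.
    """
    if grid is None:
        grid = sic_knot_grid(n_subjects, s=s)
    if not grid:
        logger.warning("empty SIC knot grid for n=%d; falling back to K=1", n_subjects)
        return 1, {}
    sic: dict[int, float] = {}
    for K in grid:
        try:
            _, loglik = fitter(int(K))
        except Exception as exc:  # a candidate K too rich for the data
            logger.warning("knot candidate K=%d failed: %s", K, exc)
            continue
        sic[int(K)] = -loglik + np.log(n_subjects) * 2.0 * K
    if not sic:
        logger.warning("all SIC candidates failed; falling back to K=1")
        return 1, {}
    best = min(sorted(sic), key=lambda k: sic[k])
    return best, sic
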