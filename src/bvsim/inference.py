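"""Cluster-bootstrap confidence intervals and fitted/prediction error metrics.

Inference resamples whole subjects with replacement (preserving the
within-cluster dependence), refits the model on each resample, and forms
percentile intervals.  Fitted errors (AAFE) use the posterior-mean random
effects E[b_i | y] = R_i1 - c_i R_i2; prediction errors (AAPE) for unseen
subjects set the random effects to their prior mean zero and add the error
mean gamma-hat, since E(Y) = mu + gamma under the SALD error law.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecm import ECMDivergenceError, FitConfig, FitResult, fit
from .model import ClusteredBivariateData

__all__ = [
    "BootstrapResult",
    "bootstrap_ci",
    "fitted_prediction_errors",
    "prediction_errors_from_fit",
]

logger = logging.getLogger(__name__)


def _param_vector(res: FitResult) -> np.ndarray:
    p = res.params
    iu2 = np.triu_indices(2)
    iuo = np.triu_indices(p.Omega.shape[0])
    return np.concatenate([p.beta1, p.beta2, p.gamma, p.Sigma[iu2], p.Omega[iuo]])


def _param_names(res: FitResult) -> list[str]:
    p = res.params
    names = [f"beta1{j + 1}" for j in range(len(p.beta1))]
    names += [f"beta2{j + 1}" for j in range(len(p.beta2))]
    names += ["gamma1", "gamma2"]
    iu2 = np.triu_indices(2)
    names += [f"Sigma{a + 1}{b + 1}" for a, b in zip(*iu2)]
    iuo = np.triu_indices(p.Omega.shape[0])
    names += [f"Omega{a + 1}{b + 1}" for a, b in zip(*iuo)]
    return names


@dataclass
class BootstrapResult:
    """Percentile bootstrap output: replicate estimates and interval bounds."""

    names: list[str]
    estimate: np.ndarray
    replicates: np.ndarray      # (B_converged, n_params)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    failures: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "estimate": self.estimate,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
            }
        )

    def write(self, path) -> None:
        self.table().to_csv(path, index=False)


def bootstrap_ci(
    data: ClusteredBivariateData,
    config: FitConfig | None = None,
    B: int = 200,
    level: float = 0.95,
    seed: int = 0,
    base_fit: FitResult | None = None,
) -> BootstrapResult:
    """Cluster bootstrap: resample subjects, refit, percentile intervals.

    The interior-knot count of the base fit is reused for the replicates.
    Deterministic given ``seed``.  More than 50% failed replicates is an
    error (usually too many knots, or too few subjects).
    """
    config = config or FitConfig()
    if base_fit is None:
        base_fit = fit(data, config)
    from dataclasses import replace

    rep_cfg = replace(config, n_interior=base_fit.n_interior)
    if B < 10:
        warnings.warn("bootstrap with B < 10 gives degenerate percentile bounds")

    rng = np.random.default_rng(seed)
    n = data.n_subjects
    rows, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            res = fit(data.subset_subjects(idx), rep_cfg)
        except (ECMDivergenceError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("bootstrap replicate failed: %s", exc)
            failures += 1
            continue
        rows.append(_param_vector(res))
    if failures > B // 2:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed to converge; "
            "consider more subjects or fewer knots"
        )
    reps = np.array(rows)
    alpha = 1.0 - level
    lower = np.quantile(reps, alpha / 2.0, axis=0)
    upper = np.quantile(reps, 1.0 - alpha / 2.0, axis=0)
    return BootstrapResult(
        names=_param_names(base_fit),
        estimate=_param_vector(base_fit),
        replicates=reps,
        ci_lower=lower,
        ci_upper=upper,
        level=level,
        failures=failures,
    )


def _fitted_values(res: FitResult, data: ClusteredBivariateData, include_skew: bool) -> np.ndarray:
    """Subject-specific fitted values using posterior-mean random effects."""
    u1 = data.x1 @ res.params.beta1
    u2 = data.x2 @ res.params.beta2
    ghat = np.column_stack([res.predict_g(1, u1), res.predict_g(2, u2)])
    bhat = res.state.r1 - res.state.c[:, None] * res.state.r2   # E[b_i | y]
    q1p = data.z1.shape[1]
    idx = data.row_subject
    re_part = np.column_stack([
        np.einsum("nj,nj->n", data.z1, bhat[idx, :q1p]),
        np.einsum("nj,nj->n", data.z2, bhat[idx, q1p:]),
    ])
    out = ghat + re_part
    if include_skew:
        out = out + res.params.gamma
    return out


def _predicted_values(
    res: FitResult, data: ClusteredBivariateData, include_skew: bool
) -> tuple[np.ndarray, int]:
    """Marginal-mean predictions for unseen subjects; counts clamped indices."""
    u1 = data.x1 @ res.params.beta1
    u2 = data.x2 @ res.params.beta2
    a1, b1 = res.basis1.support
    a2, b2 = res.basis2.support
    n_clamped = int(np.sum((u1 < a1) | (u1 > b1)) + np.sum((u2 < a2) | (u2 > b2)))
    if n_clamped:
        logger.info("%d test index values outside training support were clamped", n_clamped)
    out = np.column_stack([res.predict_g(1, u1), res.predict_g(2, u2)])
    if include_skew:
        out = out + res.params.gamma
    return out, n_clamped


def prediction_errors_from_fit(
    res: FitResult,
    train: ClusteredBivariateData,
    test: ClusteredBivariateData,
    include_skew_offset: bool = True,
) -> tuple[float, float, float, float]:
    """(AAFE1, AAFE2, AAPE1, AAPE2) for an existing fit on ``train``."""
    yhat = _fitted_values(res, train, include_skew_offset)
    aafe = np.mean(np.abs(train.y - yhat), axis=0)
    ytil, _ = _predicted_values(res, test, include_skew_offset)
    aape = np.mean(np.abs(test.y - ytil), axis=0)
    return float(aafe[0]), float(aafe[1]), float(aape[0]), float(aape[1])


def fitted_prediction_errors(
    train: ClusteredBivariateData,
    test: ClusteredBivariateData,
    config: FitConfig | None = None,
    include_skew_offset: bool = True,
) -> tuple[float, float, float, float]:
    """Fit on ``train`` and report average absolute fitted/prediction errors.

    AAFE_k averages |y - y_hat| over training members with subject-specific
    fitted values; AAPE_k averages |y - y_tilde| over test members with
    marginal-mean predictions.
    """
    res = fit(train, config or FitConfig())
    return prediction_errors_from_fit(res, train, test, include_skew_offset)
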