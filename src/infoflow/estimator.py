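"""Maximum-likelihood information-flow estimation for multivariate series.

Model
-----
The observed series are treated as a realisation of a linear stochastic
differential equation ``dX = (f + A X) dt + B dW`` with diagonal ``B``.
For each target component ``i`` the drift row ``(f_i, a_i1..a_id)`` is
estimated by maximising the Gaussian transition likelihood of the
Euler-discretised model, which reduces to the normal equations

    C a = Cdot[:, i]

in the sample covariances of :class:`~infoflow.series.CovarianceStructure`.
The information flow from ``X_j`` to ``X_i`` (in nats per unit time, or per
step when ``dt = 1``) is the plug-in of the linear-system flow
``T_{j->i} = a_ij sigma_ij / sigma_ii``:

    T_hat[j -> i] = (C_ji / C_ii) * a_hat_ij

and the influence of ``X_i`` on its own marginal entropy is the diagonal
drift coefficient ``a_hat_ii``.  The stochastic forcing contributes
``g_ii / (2 C_ii) >= 0`` to the entropy budget of ``X_i``; the three kinds
of terms sum to the marginal entropy tendency and define the normaliser

    Z_i = |a_hat_ii| + sum_{j != i} |T_hat[j->i]| + g_ii / (2 C_ii)

through which the relative (normalised) flow ``tau = T / Z`` in [-1, 1] is
obtained.

The drift solve uses a symmetric linear solve; the equivalent cofactor
expansion is kept in :mod:`infoflow.oracle` as a brute-force cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import DegenerateSeriesError, ParameterError, SingularCovarianceError
from .series import (
    CovarianceStructure,
    DerivedSeries,
    EstimatorConfig,
    TimeSeriesSet,
    covariance_structure,
    derive_series,
)

__all__ = [
    "DriftFit",
    "FlowMatrixResult",
    "EntropyBudget",
    "fit_drift",
    "flow_pair",
    "bivariate_flow",
    "self_influence",
    "entropy_decomposition",
    "normalize_flows",
    "flow_matrix",
]

#: reciprocal condition number below which C is treated as singular
_RCOND_MIN = 1e-12


@dataclass(frozen=True)
class DriftFit:
    """MLE of one drift row of the linear model.

    ``coeffs[j]`` estimates ``a_ij`` (units 1/time); ``intercept`` is
    ``f_i``; ``noise_g`` is ``g_ii = b_ii^2`` (units of X_i^2 per time);
    ``residual_q`` the residual sum of squares of the derived-series
    regression.  ``dt_eff = k * dt`` is the likelihood step.
    """

    target: int
    coeffs: np.ndarray
    intercept: float
    noise_g: float
    residual_q: float
    dt_eff: float
    n_eff: int


@dataclass(frozen=True)
class EntropyBudget:
    """Additive decomposition of a component's marginal entropy tendency."""

    target: int
    self_rate: float
    flows: np.ndarray  # length d; entry at the target itself is 0
    noise: float

    @property
    def total(self) -> float:
        return self.self_rate + float(self.flows.sum()) + self.noise


@dataclass(frozen=True)
class FlowMatrixResult:
    """All pairwise flows with uncertainties for one series set.

    ``T[j, i]`` is the signed flow from variable j (source, row) to variable
    i (target, column); the diagonal is 0 by convention with the
    self-influence kept in ``dH_self``.  ``tau`` is the normalised flow,
    ``se_T``/``p_T`` the asymptotic standard errors and two-sided p-values,
    and ``significant``/``self_significant`` the test masks after the
    configured multiplicity correction.
    """

    names: tuple[str, ...]
    T: np.ndarray
    tau: np.ndarray
    Z: np.ndarray
    dH_self: np.ndarray
    dH_noise: np.ndarray
    se_T: np.ndarray
    p_T: np.ndarray
    se_self: np.ndarray
    p_self: np.ndarray
    significant: np.ndarray
    self_significant: np.ndarray
    config: EstimatorConfig

    @property
    def n_vars(self) -> int:
        return self.T.shape[0]


def _check_conditioning(C: np.ndarray) -> None:
    rcond = 1.0 / np.linalg.cond(C)
    if not np.isfinite(rcond) or rcond < _RCOND_MIN:
        raise SingularCovarianceError(
            "sample covariance matrix is numerically singular (collinear or "
            "near-constant columns); for simulated input re-run with another "
            "seed, for observed data remove the collinear columns"
        )


def fit_drift(cov: CovarianceStructure, target: int) -> DriftFit:
    """MLE of the drift row for one target component.

    Solves the normal equations ``C a = Cdot[:, target]`` (numerically
    equivalent to the cofactor form, since C is symmetric), then recovers
    the intercept from the means and the noise amplitude from the residual
    sum, which is itself evaluated from covariances alone:

        Q = n_eff * (var(dX_i) - 2 a.Cdot[:,i] + a.C.a)
        g_ii = Q * dt_eff / n_eff
    """
    d = cov.n_vars
    if not 0 <= target < d:
        raise ParameterError(f"target index {target} out of range for d={d}")
    _check_conditioning(cov.C)
    rhs = cov.Cdot[:, target]
    coeffs = linalg.solve(cov.C, rhs, assume_a="sym")
    dt_eff = cov.k * cov.dt
    q = cov.n_eff * (cov.dvar[target] - 2.0 * coeffs @ rhs + coeffs @ cov.C @ coeffs)
    q = max(float(q), 0.0)  # exact fits can round slightly negative
    g = q * dt_eff / cov.n_eff
    intercept = float(cov.xdotbar[target] - coeffs @ cov.xbar)
    return DriftFit(
        target=int(target),
        coeffs=coeffs,
        intercept=intercept,
        noise_g=g,
        residual_q=q,
        dt_eff=dt_eff,
        n_eff=cov.n_eff,
    )


def flow_pair(cov: CovarianceStructure, fit: DriftFit, source: int) -> float:
    """Signed information flow from ``source`` into the fitted target."""
    i = fit.target
    if source == i:
        raise ParameterError("source equals target; use self_influence for the self term")
    if not 0 <= source < cov.n_vars:
        raise ParameterError(f"source index {source} out of range")
    return float(cov.C[source, i] / cov.C[i, i] * fit.coeffs[source])


def self_influence(fit: DriftFit) -> float:
    """The component's influence on its own marginal entropy, ``a_hat_ii``."""
    return float(fit.coeffs[fit.target])


def bivariate_flow(
    x1: np.ndarray, x2: np.ndarray, k: int = 1, dt: float = 1.0
) -> float:
    """Flow from ``x2`` into ``x1`` from the closed-form two-series estimator.

    Built literally from the five sample statistics

        (C11 C12 C2,d1 - C12^2 C1,d1) / (C11^2 C22 - C11 C12^2),

    where ``Ci,d1`` is the covariance of X_i with the derived series of X_1.
    Algebraically identical to the d=2 case of the multivariate estimator;
    kept as an independent code path.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ParameterError("x1 and x2 must be 1-D arrays of equal length")
    n = x1.size
    if not 1 <= k <= n - 2:
        raise ParameterError(f"k must satisfy 1 <= k <= N-2 = {n - 2}, got {k}")
    d1 = (x1[k:] - x1[:-k]) / (k * dt)
    a1, a2 = x1[: n - k], x2[: n - k]
    a1 = a1 - a1.mean()
    a2 = a2 - a2.mean()
    d1 = d1 - d1.mean()
    m = n - k
    c11 = a1 @ a1 / m
    c22 = a2 @ a2 / m
    c12 = a1 @ a2 / m
    c1d1 = a1 @ d1 / m
    c2d1 = a2 @ d1 / m
    if c11 <= 0 or c22 <= 0:
        raise DegenerateSeriesError("zero-variance series in bivariate flow")
    denom = c11 * c11 * c22 - c11 * c12 * c12
    if denom == 0.0:
        raise SingularCovarianceError("the two series are perfectly collinear")
    return float((c11 * c12 * c2d1 - c12 * c12 * c1d1) / denom)


def entropy_decomposition(
    cov: CovarianceStructure, fit: DriftFit
) -> EntropyBudget:
    """Split the marginal entropy tendency of the target into self + flows + noise."""
    i = fit.target
    d = cov.n_vars
    flows = np.zeros(d)
    for j in range(d):
        if j != i:
            flows[j] = flow_pair(cov, fit, j)
    noise = 0.5 * fit.noise_g / cov.C[i, i]
    return EntropyBudget(target=i, self_rate=self_influence(fit), flows=flows, noise=noise)


def normalize_flows(
    flows: np.ndarray, self_rate: float, noise: float
) -> tuple[float, np.ndarray]:
    """Normaliser ``Z`` and relative flows ``tau`` for one target.

    ``Z = |self| + sum|flows| + noise`` so that every ``|tau| <= 1`` by
    construction; ``tau`` keeps the sign of the flow.
    """
    z = abs(self_rate) + float(np.abs(flows).sum()) + noise
    if z == 0.0:
        raise DegenerateSeriesError(
            "normaliser is zero: no dynamics, flows, or noise for this target"
        )
    return z, flows / z


def flow_matrix(x: TimeSeriesSet, config: EstimatorConfig | None = None) -> FlowMatrixResult:
    """Estimate every ordered-pair flow, self-influence, and normalised flow.

    Deterministic given the input series and configuration.  Significance
    comes from the per-target Fisher information (see
    :mod:`infoflow.significance`).
    """
    from . import significance as _sig  # local import to avoid a cycle

    cfg = config or EstimatorConfig()
    xdot = derive_series(x, cfg.k)
    cov = covariance_structure(x, xdot)
    d = x.n_vars
    x_aligned = x.values[: cov.n_eff]

    T = np.zeros((d, d))
    se_T = np.zeros((d, d))
    p_T = np.ones((d, d))
    dH_self = np.zeros(d)
    dH_noise = np.zeros(d)
    se_self = np.zeros(d)
    p_self = np.ones(d)
    Z = np.zeros(d)
    tau = np.zeros((d, d))

    for i in range(d):
        fit = fit_drift(cov, i)
        fisher = _sig.fisher_information(x_aligned, xdot.values[:, i], fit)
        budget = entropy_decomposition(cov, fit)
        dH_self[i] = budget.self_rate
        dH_noise[i] = budget.noise
        T[:, i] = budget.flows
        Z[i], tau[:, i] = normalize_flows(budget.flows, budget.self_rate, budget.noise)
        se_self[i], _, p_self[i] = _sig.self_significance(fisher, cfg.alpha)
        for j in range(d):
            if j == i:
                continue
            se_T[j, i], _, p_T[j, i] = _sig.flow_significance(
                T[j, i], fisher, cov, j, cfg.alpha
            )

    significant = _sig.apply_correction(p_T, cfg.correction, cfg.alpha)
    self_significant = p_self < cfg.alpha
    return FlowMatrixResult(
        names=x.names,
        T=T,
        tau=tau,
        Z=Z,
        dH_self=dH_self,
        dH_noise=dH_noise,
        se_T=se_T,
        p_T=p_T,
        se_self=se_self,
        p_self=p_self,
        significant=significant,
        self_significant=self_significant,
        config=cfg,
    )
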