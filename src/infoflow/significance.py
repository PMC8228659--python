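"""Asymptotic uncertainty for flow and self-influence estimates.

For each target component the parameter vector is
``theta = (f_i, a_i1..a_id, b_i)`` with ``b_i = sqrt(g_ii)``.  The Fisher
information is the empirical average of the negative Hessian of the
per-step Gaussian transition log-density

    log rho(X_{n+1} | X_n) = -log b - (1/2) log(2 pi dt_eff)
                             - dt_eff * R_n^2 / (2 b^2),
    R_n = dXdt_i,n - (f_i + sum_j a_ij X_j,n),

evaluated at the MLE; ``(n_eff I)^{-1}`` is the asymptotic covariance of
``theta_hat``.  A flow estimate ``T = (C_ji/C_ii) a_ij`` then carries the
standard error ``|C_ji/C_ii| * sd(a_ij)``, treating the covariance ratio as
fixed — the large-sample approximation under which the estimates are
normal.  The Hessian is closed-form; ``transition_loglik`` is exposed so a
finite-difference Hessian can cross-check it.

Caveat: because the covariance ratio is treated as fixed, these error bars
are exact for testing *zero* flow (they reduce to the t-test on ``a_ij``)
but understate the spread of strongly nonzero flow estimates; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimator import DriftFit
from .exceptions import ParameterError, SingularInformationError
from .series import CovarianceStructure

__all__ = [
    "FisherInfo",
    "SignificanceReport",
    "transition_loglik",
    "fisher_information",
    "flow_significance",
    "self_significance",
    "apply_correction",
]


@dataclass(frozen=True)
class FisherInfo:
    """Empirical Fisher information for one target's parameter vector."""

    target: int
    theta_hat: np.ndarray  # (f, a_1..a_d, b)
    info: np.ndarray  # (d+2) x (d+2)
    cov_theta: np.ndarray  # inverse of (n_eff * info)


@dataclass(frozen=True)
class SignificanceReport:
    """Standard errors, confidence bounds and p-values for a flow matrix."""

    se_T: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    p_T: np.ndarray
    se_self: np.ndarray
    ci_self_lo: np.ndarray
    ci_self_hi: np.ndarray
    p_self: np.ndarray
    significant: np.ndarray
    self_significant: np.ndarray
    alpha: float
    correction: str


def transition_loglik(
    theta: np.ndarray, x_aligned: np.ndarray, xdot_i: np.ndarray, dt_eff: float
) -> float:
    """Total Gaussian transition log-likelihood for one target (up to data terms)."""
    theta = np.asarray(theta, dtype=float)
    f, a, b = theta[0], theta[1:-1], theta[-1]
    r = xdot_i - (f + x_aligned @ a)
    n = x_aligned.shape[0]
    return float(
        -n * np.log(b)
        - 0.5 * n * np.log(2.0 * np.pi * dt_eff)
        - dt_eff * (r @ r) / (2.0 * b * b)
    )


def fisher_information(
    x_aligned: np.ndarray, xdot_i: np.ndarray, fit: DriftFit
) -> FisherInfo:
    """Closed-form empirical Fisher information at the fitted parameters.

    Blocks (u = (1, X_1..X_d) per step, R the residual, b^2 = g):

    * (f,a)-block: ``(dt_eff / b^2) * mean(u u')``
    * (f,a)-b cross: ``(2 dt_eff / b^3) * mean(R u)`` (≈0 at the MLE)
    * b-b: ``-1/b^2 + 3 dt_eff * mean(R^2) / b^4``
    """
    n, d = x_aligned.shape
    dt_eff = fit.dt_eff
    u = np.column_stack([np.ones(n), x_aligned])
    r = xdot_i - u @ np.concatenate([[fit.intercept], fit.coeffs])
    # g recomputed from the residuals (identical to fit.noise_g up to its
    # clamp) keeps the exact MLE identity I_bb = 2/g > 0; an exactly zero
    # residual (perfectly deterministic linear input) falls through to the
    # singular-information error below
    g = max(dt_eff * float(r @ r) / n, 1e-250)
    b = np.sqrt(g)
    info = np.empty((d + 2, d + 2))
    info[: d + 1, : d + 1] = (dt_eff / g) * (u.T @ u) / n
    cross = (2.0 * dt_eff / b**3) * (r[:, None] * u).mean(axis=0)
    info[: d + 1, d + 1] = cross
    info[d + 1, : d + 1] = cross
    info[d + 1, d + 1] = -1.0 / g + 3.0 * dt_eff * float(r @ r) / n / g**2
    theta_hat = np.concatenate([[fit.intercept], fit.coeffs, [b]])
    # invert with diagonal preconditioning: the blocks differ by many orders
    # of magnitude (1/g vs second moments), and a raw inverse can round the
    # smallest variances below zero
    diag = np.diag(info)
    if not np.all(diag > 0):
        raise SingularInformationError(
            "Fisher information is not positive definite at the fit"
        )
    scale = np.sqrt(diag)
    unit = info / np.outer(scale, scale)
    try:
        unit_inv = np.linalg.inv(unit)
    except np.linalg.LinAlgError as err:
        raise SingularInformationError(
            "Fisher information is singular (collinear regressors)"
        ) from err
    cov_theta = unit_inv / np.outer(scale, scale) / n
    if not np.all(np.diag(cov_theta) > 0):
        raise SingularInformationError(
            "Fisher information is not positive definite at the fit"
        )
    return FisherInfo(target=fit.target, theta_hat=theta_hat, info=info, cov_theta=cov_theta)


def _z(alpha: float) -> float:
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def flow_significance(
    T_hat: float,
    fisher: FisherInfo,
    cov: CovarianceStructure,
    source: int,
    alpha: float = 0.10,
) -> tuple[float, tuple[float, float], float]:
    """Standard error, (1-alpha) CI and two-sided p-value for one flow estimate."""
    i = fisher.target
    if source == i:
        raise ParameterError("source equals target")
    var_a = fisher.cov_theta[1 + source, 1 + source]
    se = abs(cov.C[source, i] / cov.C[i, i]) * float(np.sqrt(var_a))
    z = _z(alpha)
    ci = (T_hat - z * se, T_hat + z * se)
    p = 1.0 if se == 0.0 and T_hat == 0.0 else float(2.0 * stats.norm.sf(abs(T_hat) / max(se, 1e-300)))
    return se, ci, p


def self_significance(
    fisher: FisherInfo, alpha: float = 0.10
) -> tuple[float, tuple[float, float], float]:
    """Standard error, CI and p-value for the self-influence (diagonal drift) estimate."""
    i = fisher.target
    a_ii = float(fisher.theta_hat[1 + i])
    se = float(np.sqrt(fisher.cov_theta[1 + i, 1 + i]))
    z = _z(alpha)
    ci = (a_ii - z * se, a_ii + z * se)
    p = 1.0 if se == 0.0 and a_ii == 0.0 else float(2.0 * stats.norm.sf(abs(a_ii) / max(se, 1e-300)))
    return se, ci, p


def apply_correction(
    p_T: np.ndarray, method: str = "none", alpha: float = 0.10
) -> np.ndarray:
    """Boolean significance mask over the off-diagonal flow p-values.

    ``none`` tests each edge at level alpha as in the original graph
    algorithm; ``bonferroni`` and ``benjamini_hochberg`` control FWER / FDR
    over the d(d-1) simultaneous edge tests.
    """
    d = p_T.shape[0]
    off = ~np.eye(d, dtype=bool)
    mask = np.zeros((d, d), dtype=bool)
    pvals = p_T[off]
    if method == "none":
        rej = pvals < alpha
    elif method == "bonferroni":
        rej = multipletests(pvals, alpha=alpha, method="bonferroni")[0]
    elif method == "benjamini_hochberg":
        rej = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        raise ParameterError(f"unknown correction method {method!r}")
    mask[off] = rej
    return mask


def significance_report(
    result, alpha: float | None = None, correction: str | None = None
) -> SignificanceReport:
    """Bundle the uncertainty fields of a FlowMatrixResult into a report."""
    alpha = result.config.alpha if alpha is None else alpha
    correction = result.config.correction if correction is None else correction
    z = _z(alpha)
    significant = apply_correction(result.p_T, correction, alpha)
    return SignificanceReport(
        se_T=result.se_T,
        ci_lo=result.T - z * result.se_T,
        ci_hi=result.T + z * result.se_T,
        p_T=result.p_T,
        se_self=result.se_self,
        ci_self_lo=result.dH_self - z * result.se_self,
        ci_self_hi=result.dH_self + z * result.se_self,
        p_self=result.p_self,
        significant=significant,
        self_significant=result.p_self < alpha,
        alpha=alpha,
        correction=correction,
    )
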