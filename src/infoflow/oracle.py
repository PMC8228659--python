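"""Closed-form references for linear systems, and the brute-force estimator path.

For a stable linear SDE ``dX = (f + A X) dt + B dW`` the stationary
covariance ``Sigma`` solves the continuous Lyapunov equation

    A Sigma + Sigma A' + B B' = 0,

and the exact information flow from X_j to X_i is

    T[j -> i] = a_ij * sigma_ij / sigma_ii.

These closed forms let the time-series estimator be validated on systems
whose true flows are known, including the correlation-without-causation
configuration (a confounder makes sigma_ij nonzero while both direct flows
are exactly zero).  The module also carries the determinant/cofactor form
of the drift estimator — mathematically identical to the linear-solve path
used by :mod:`infoflow.estimator`, retained as an independent brute-force
cross-check for small d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import ParameterError, UnstableSystemError
from .series import CovarianceStructure

__all__ = [
    "LinearSystemTruth",
    "stationary_covariance",
    "true_flow",
    "cofactor_coefficient",
    "cofactor_estimator",
]


@dataclass(frozen=True)
class LinearSystemTruth:
    """Drift, diffusion, stationary covariance and exact flow matrix of a linear SDE."""

    A: np.ndarray
    BBT: np.ndarray
    Sigma: np.ndarray
    T_true: np.ndarray  # T_true[j, i] = flow j -> i; zero diagonal

    @classmethod
    def from_system(cls, A: np.ndarray, BBT: np.ndarray) -> "LinearSystemTruth":
        A = np.asarray(A, dtype=float)
        BBT = np.asarray(BBT, dtype=float)
        Sigma = stationary_covariance(A, BBT)
        return cls(A=A, BBT=BBT, Sigma=Sigma, T_true=true_flow(A, Sigma))


def stationary_covariance(A: np.ndarray, BBT: np.ndarray) -> np.ndarray:
    """Stationary covariance of a stable linear SDE via the Lyapunov equation."""
    A = np.asarray(A, dtype=float)
    BBT = np.asarray(BBT, dtype=float)
    if np.real(np.linalg.eigvals(A)).max() >= 0.0:
        raise UnstableSystemError(
            "drift matrix has an eigenvalue with non-negative real part; "
            "no stationary distribution exists"
        )
    Sigma = linalg.solve_continuous_lyapunov(A, -BBT)
    return 0.5 * (Sigma + Sigma.T)


def true_flow(A: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Exact flow matrix ``T[j, i] = a_ij sigma_ij / sigma_ii`` (zero diagonal)."""
    A = np.asarray(A, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    T = A.T * Sigma / np.diag(Sigma)
    np.fill_diagonal(T, 0.0)
    return T


def _det_minor_expansion(M: np.ndarray) -> float:
    """Determinant by recursive first-row minor expansion (brute force on purpose)."""
    n = M.shape[0]
    if n == 1:
        return float(M[0, 0])
    total = 0.0
    cols = np.arange(n)
    for j in range(n):
        minor = M[1:][:, cols != j]
        total += ((-1.0) ** j) * M[0, j] * _det_minor_expansion(minor)
    return total


def _cofactor(M: np.ndarray, i: int, j: int) -> float:
    n = M.shape[0]
    rows = np.arange(n) != i
    cols = np.arange(n) != j
    return ((-1.0) ** (i + j)) * _det_minor_expansion(M[rows][:, cols])


def cofactor_coefficient(cov: CovarianceStructure, target: int, j: int) -> float:
    """Drift coefficient ``a_hat_{target,j}`` by the explicit cofactor formula.

    ``a_hat_{1i} = (1/det C) * sum_l Delta_il C_{l,d1}`` with Delta the
    cofactors of C.  Exponential cost; intended for d <= 6 cross-checks.
    """
    d = cov.n_vars
    if d > 6:
        raise ParameterError("cofactor path is a brute-force reference for d <= 6")
    det = _det_minor_expansion(cov.C)
    total = 0.0
    for l in range(d):
        total += _cofactor(cov.C, j, l) * cov.Cdot[l, target]
    return total / det


def cofactor_estimator(cov: CovarianceStructure, target: int, source: int) -> float:
    """Flow from ``source`` to ``target`` via determinants and cofactors.

    Must agree with the linear-solve path of
    :func:`infoflow.estimator.flow_pair` to floating precision on
    well-conditioned inputs.
    """
    if source == target:
        raise ParameterError("source equals target")
    a = cofactor_coefficient(cov, target, source)
    return float(cov.C[source, target] / cov.C[target, target] * a)
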