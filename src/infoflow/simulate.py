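"""Benchmark data generators.

Three families of test systems:

* a vector autoregressive (VAR) network ``X(n+1) = alpha + A X(n) + B e(n+1)``
  with independent standard normal shocks, including the six-node benchmark
  network with two directed cycles, (X1,X2,X3) and (X4,X5), both driven by
  the confounder X6;
* general linear stochastic differential equations integrated by
  Euler-Maruyama;
* a triad of chaotic Rossler oscillators (9 equations) in a master-slave
  configuration, X -> Y and X -> Z with tunable coupling, integrated by
  fixed-step second-order Runge-Kutta (Heun).  For coupling above ~0.15 the
  slaves nearly synchronise with the master, the regime where
  correlation-based inference breaks down.

All generators are seed-deterministic: the same spec yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .exceptions import ParameterError, SimulationBlowUpError
from .series import TimeSeriesSet

__all__ = [
    "VARSpec",
    "SDESpec",
    "RosslerSpec",
    "benchmark_var_spec",
    "simulate_var",
    "simulate_linear_sde",
    "simulate_rossler",
]

#: coefficient matrix of the six-node benchmark network (row i = equation i)
BENCHMARK_A = np.array(
    [
        [0.0, 0.0, -0.6, 0.0, 0.0, 0.0],
        [-0.5, 0.0, 0.0, 0.0, 0.0, 0.8],
        [0.0, 0.7, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.7, 0.4, 0.0],
        [0.0, 0.0, 0.0, 0.2, 0.0, 0.7],
        [0.0, 0.0, 0.0, 0.0, 0.0, -0.5],
    ]
)

#: intercept vector of the benchmark network
BENCHMARK_ALPHA = np.array([0.1, 0.7, 0.5, 0.2, 0.8, 0.3])


@dataclass(frozen=True)
class VARSpec:
    """Parameters of a VAR(1) map ``X(n+1) = alpha + A X(n) + diag(noise_amp) e``."""

    A: np.ndarray
    intercept: np.ndarray
    noise_amp: np.ndarray
    N: int
    seed: int
    burn_in: int = 0

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        d = A.shape[0]
        if A.shape != (d, d):
            raise ParameterError("A must be square")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "intercept", _as_vec(self.intercept, d, "intercept"))
        amp = _as_vec(self.noise_amp, d, "noise_amp")
        if (amp < 0).any():
            raise ParameterError("noise_amp must be non-negative")
        object.__setattr__(self, "noise_amp", amp)
        if self.N < 1 or self.burn_in < 0:
            raise ParameterError("N must be >= 1 and burn_in >= 0")
        if np.abs(np.linalg.eigvals(A)).max() >= 1.0:
            warnings.warn("spectral radius of A >= 1: the VAR map is not stationary")


@dataclass(frozen=True)
class SDESpec:
    """Parameters of a linear SDE ``dX = (f + A X) dt + diag(noise_amp) dW``."""

    A: np.ndarray
    f: np.ndarray
    noise_amp: np.ndarray
    dt: float
    N: int
    seed: int
    burn_in: int = 0

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        d = A.shape[0]
        if A.shape != (d, d):
            raise ParameterError("A must be square")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "f", _as_vec(self.f, d, "f"))
        amp = _as_vec(self.noise_amp, d, "noise_amp")
        if (amp < 0).any():
            raise ParameterError("noise_amp must be non-negative")
        object.__setattr__(self, "noise_amp", amp)
        if self.dt <= 0 or self.N < 1 or self.burn_in < 0:
            raise ParameterError("dt must be > 0, N >= 1, burn_in >= 0")
        if np.real(np.linalg.eigvals(A)).max() >= 0.0:
            warnings.warn("drift matrix A is not stable: no stationary distribution")


@dataclass(frozen=True)
class RosslerSpec:
    """Master-slave Rossler triad with coupling ``eps`` into the slaves' x-equations.

    The defaults are the benchmark conditions: natural frequencies
    (1.015, 0.985, 0.95), step 0.001, 50,000 integration steps with the
    first 10,000 discarded, and the initial state drawn uniformly from
    [-1, 1]^9.
    """

    eps: float = 0.0
    omega: tuple[float, float, float] = (1.015, 0.985, 0.95)
    dt: float = 0.001
    n_steps: int = 50_000
    discard: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ParameterError("eps must be >= 0")
        if not 0 <= self.discard < self.n_steps:
            raise ParameterError("discard must satisfy 0 <= discard < n_steps")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")


def _as_vec(v, d: int, name: str) -> np.ndarray:
    out = np.broadcast_to(np.asarray(v, dtype=float), (d,)).copy()
    if out.shape != (d,):
        raise ParameterError(f"{name} must broadcast to length {d}")
    return out


def benchmark_var_spec(noise_amp: float = 1.0, N: int = 10_000, seed: int = 0) -> VARSpec:
    """The six-node cyclic/confounded benchmark network preset."""
    return VARSpec(
        A=BENCHMARK_A,
        intercept=BENCHMARK_ALPHA,
        noise_amp=np.full(6, float(noise_amp)),
        N=N,
        seed=seed,
    )


def simulate_var(spec: VARSpec) -> TimeSeriesSet:
    """Iterate the VAR map from a standard-normal initial state; dt = 1."""
    rng = np.random.default_rng(spec.seed)
    d = spec.A.shape[0]
    x = rng.standard_normal(d)
    shocks = rng.standard_normal((spec.burn_in + spec.N, d)) * spec.noise_amp
    A, a = spec.A, spec.intercept
    out = np.empty((spec.N, d))
    for n in range(spec.burn_in + spec.N):
        x = a + A @ x + shocks[n]
        if n >= spec.burn_in:
            out[n - spec.burn_in] = x
    _check_finite(out)
    return TimeSeriesSet(values=out, dt=1.0, names=tuple(f"X{i+1}" for i in range(d)))


def simulate_linear_sde(spec: SDESpec) -> TimeSeriesSet:
    """Euler-Maruyama path of the linear SDE, started from the origin."""
    rng = np.random.default_rng(spec.seed)
    d = spec.A.shape[0]
    x = np.zeros(d)
    total = spec.burn_in + spec.N
    noise = rng.standard_normal((total, d)) * (spec.noise_amp * np.sqrt(spec.dt))
    A, f, dt = spec.A, spec.f, spec.dt
    out = np.empty((spec.N, d))
    for n in range(total):
        x = x + (f + A @ x) * dt + noise[n]
        if n >= spec.burn_in:
            out[n - spec.burn_in] = x
    _check_finite(out)
    return TimeSeriesSet(values=out, dt=dt, names=tuple(f"X{i+1}" for i in range(d)))


def _rossler_rhs(u: np.ndarray, om: tuple[float, float, float], eps: float) -> np.ndarray:
    x1, x2, x3, y1, y2, y3, z1, z2, z3 = u
    return np.array(
        [
            -om[0] * x2 - x3,
            om[0] * x1 + 0.15 * x2,
            0.2 + x3 * (x1 - 10.0),
            -om[1] * y2 - y3 + eps * (x1 - y1),
            om[1] * y1 + 0.15 * y2,
            0.2 + y3 * (y1 - 10.0),
            -om[2] * z2 - z3 + eps * (x1 - z1),
            om[2] * z1 + 0.15 * z2,
            0.2 + z3 * (z1 - 10.0),
        ]
    )


#: column names of the full 9-dimensional Rossler state
ROSSLER_NAMES = ("x1", "x2", "x3", "y1", "y2", "y3", "z1", "z2", "z3")


def simulate_rossler(spec: RosslerSpec, full_state: bool = False) -> TimeSeriesSet:
    """Integrate the coupled Rossler triad with fixed-step Heun (RK2).

    Returns the three first components (x1, y1, z1) that represent the
    oscillators, or the full 9-column state with ``full_state=True`` (the
    multivariate estimator needs the full state to resolve the rotational
    dynamics).  Raises :class:`SimulationBlowUpError` if the trajectory
    leaves the finite range — re-run with another seed.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(-1.0, 1.0, 9)
    om, eps, dt = spec.omega, spec.eps, spec.dt
    out = np.empty((spec.n_steps, 9))
    for n in range(spec.n_steps):
        k1 = _rossler_rhs(u, om, eps)
        k2 = _rossler_rhs(u + dt * k1, om, eps)
        u = u + 0.5 * dt * (k1 + k2)
        out[n] = u
    kept = out[spec.discard :]
    if not np.isfinite(kept).all() or np.abs(kept).max() > 1e6:
        raise SimulationBlowUpError(
            "trajectory blew up from this initial state; re-run with another seed"
        )
    if full_state:
        return TimeSeriesSet(values=kept, dt=dt, names=ROSSLER_NAMES)
    return TimeSeriesSet(values=kept[:, [0, 3, 6]], dt=dt, names=("x1", "y1", "z1"))


def _check_finite(out: np.ndarray) -> None:
    if not np.isfinite(out).all():
        raise SimulationBlowUpError("simulated trajectory diverged (non-finite values)")
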