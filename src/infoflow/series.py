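"""Multivariate series container, forward differencing, and sufficient statistics.

The estimator in :mod:`infoflow.estimator` is a function of a handful of
sample moments only: the covariance matrix ``C`` of the observed series, the
covariances ``Cdot`` between each series and each forward-differenced
("derived") series, and the corresponding means.  This module owns the data
model for the raw series and computes those sufficient statistics.

Conventions
-----------
* ``values`` matrices are N rows (time) x d columns (variables).
* The derived series over span ``k`` is ``(X[n+k] - X[n]) / (k * dt)``,
  defined for ``n = 0 .. N-k-1``.
* All sample statistics are taken over the *aligned* range: the raw series
  truncated to its first ``N - k`` rows, paired row-for-row with the derived
  series.  Mixing supports would bias ``Cdot``.
* Covariances use the maximum-likelihood ``1/n`` normalisation.  The flow
  estimator is a ratio of covariances, so the normalisation cancels there;
  it only enters the noise-amplitude estimate, where ``1/n`` matches the
  likelihood derivation.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from .exceptions import (
    DataError,
    DegenerateSeriesError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "TimeSeriesSet",
    "EstimatorConfig",
    "DerivedSeries",
    "CovarianceStructure",
    "load_series",
    "derive_series",
    "covariance_structure",
]

_CORRECTIONS = ("none", "bonferroni", "benjamini_hochberg")


@dataclass(frozen=True)
class TimeSeriesSet:
    """An equally spaced multivariate time series.

    Parameters
    ----------
    values:
        Observation matrix, N rows (time) by d columns (variables).
    dt:
        Time units per step, > 0.  Use ``dt=1`` for discrete maps, in which
        case flows come out in nats per step.
    names:
        d unique variable identifiers.
    """

    values: np.ndarray
    dt: float
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataError(f"expected a 2-D observation matrix, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        n, d = values.shape
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(f"non-finite value at row {bad[0] + 1}, column {bad[1] + 1}")
        if n < d + 2:
            raise InsufficientDataError(
                f"need at least d + 2 = {d + 2} observations for d = {d} variables, got {n}"
            )
        if not self.dt > 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        names = tuple(str(s) for s in self.names)
        if len(names) != d:
            raise DataError(f"{len(names)} names for {d} columns")
        if len(set(names)) != d:
            dupes = sorted({s for s in names if names.count(s) > 1})
            raise DataError(f"duplicate variable names: {dupes}")
        object.__setattr__(self, "names", names)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EstimatorConfig:
    """Estimation settings: differencing span, test level, multiplicity correction.

    ``k=1`` is the accurate default; ``k=2`` is appropriate for deterministic
    chaos sampled at the integration resolution (see docs/methods.md).
    """

    k: int = 1
    alpha: float = 0.10
    correction: str = "none"

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ParameterError(f"k must be an integer >= 1, got {self.k!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.correction not in _CORRECTIONS:
            raise ParameterError(
                f"correction must be one of {_CORRECTIONS}, got {self.correction!r}"
            )


@dataclass(frozen=True)
class DerivedSeries:
    """Forward-difference approximation of the time derivative over span k."""

    values: np.ndarray
    k: int
    dt: float


@dataclass(frozen=True)
class CovarianceStructure:
    """Sufficient statistics of the flow estimator.

    Attributes
    ----------
    C:
        d x d sample covariance of the (aligned) series; symmetric PSD.
    Cdot:
        d x d matrix with ``Cdot[l, i] = cov(X_l, dX_i/dt)``.  Generally
        *not* symmetric — its asymmetry is where directionality lives.
    dvar:
        d-vector of derived-series variances (needed for the residual sum).
    xbar, xdotbar:
        Sample means of the aligned series and of the derived series.
    n_eff:
        Number of aligned rows (N - k).
    k, dt:
        Echo of the differencing span and step used to build the statistics.
    """

    C: np.ndarray
    Cdot: np.ndarray
    dvar: np.ndarray
    xbar: np.ndarray
    xdotbar: np.ndarray
    n_eff: int
    k: int
    dt: float
    names: tuple[str, ...] = field(default=())

    @property
    def n_vars(self) -> int:
        return self.C.shape[0]


def load_series(
    source: str | os.PathLike | IO[str],
    dt: float,
    *,
    delimiter: str | None = None,
) -> TimeSeriesSet:
    """Read a delimited text table (comma or tab, auto-detected) into a series set.

    An optional single header row supplies variable names; otherwise columns
    are named ``X1..Xd``.  Missing or non-numeric cells are rejected with the
    offending row/column named — the estimator assumes complete, equally
    spaced series, and silent imputation would distort the covariances.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError("empty input table")
    if delimiter is None:
        delimiter = "\t" if lines[0].count("\t") >= lines[0].count(",") else ","

    def _tokens(line: str) -> list[str]:
        return [t.strip() for t in line.split(delimiter)]

    first = _tokens(lines[0])

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
        except ValueError:
            return False
        return True

    has_header = not all(_is_number(t) for t in first)
    names: Sequence[str] | None = first if has_header else None
    body = lines[1:] if has_header else lines

    d = len(first)
    rows = np.empty((len(body), d), dtype=float)
    for r, line in enumerate(body):
        toks = _tokens(line)
        if len(toks) != d:
            raise DataError(f"row {r + 1} has {len(toks)} cells, expected {d}")
        for c, tok in enumerate(toks):
            if tok == "" or not _is_number(tok):
                raise DataError(f"non-numeric cell at row {r + 1}, column {c + 1}: {tok!r}")
            rows[r, c] = float(tok)
    if names is None:
        names = [f"X{i + 1}" for i in range(d)]
    return TimeSeriesSet(values=rows, dt=float(dt), names=tuple(names))


def derive_series(x: TimeSeriesSet, k: int = 1) -> DerivedSeries:
    """Euler-forward derived series: ``(X[n+k] - X[n]) / (k dt)``, length N - k."""
    n = x.n_obs
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= n - 2):
        raise ParameterError(f"k must satisfy 1 <= k <= N-2 = {n - 2}, got {k!r}")
    vals = (x.values[k:] - x.values[:-k]) / (k * x.dt)
    return DerivedSeries(values=vals, k=int(k), dt=x.dt)


def covariance_structure(x: TimeSeriesSet, xdot: DerivedSeries) -> CovarianceStructure:
    """Sample covariances of the aligned series/derived-series pair.

    ``C`` is symmetrised by averaging with its transpose to remove float
    round-off; ``Cdot`` is left as computed.
    """
    k = xdot.k
    n_eff = x.n_obs - k
    if xdot.values.shape != (n_eff, x.n_vars):
        raise ParameterError("derived series does not match the source series and span")
    xa = x.values[:n_eff]
    xbar = xa.mean(axis=0)
    xdotbar = xdot.values.mean(axis=0)
    xc = xa - xbar
    dc = xdot.values - xdotbar
    C = xc.T @ xc / n_eff
    C = 0.5 * (C + C.T)
    zero_var = np.flatnonzero(np.diag(C) <= 0.0)
    if zero_var.size:
        bad = ", ".join(x.names[i] for i in zero_var)
        raise DegenerateSeriesError(f"zero-variance column(s): {bad}")
    Cdot = xc.T @ dc / n_eff
    dvar = np.einsum("ni,ni->i", dc, dc) / n_eff
    return CovarianceStructure(
        C=C,
        Cdot=Cdot,
        dvar=dvar,
        xbar=xbar,
        xdotbar=xdotbar,
        n_eff=n_eff,
        k=k,
        dt=x.dt,
        names=x.names,
    )
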