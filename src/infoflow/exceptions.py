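"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`InfoFlowError`, so callers (and the CLI) can distinguish user/data
problems from genuine bugs.
"""


class InfoFlowError(Exception):
    """Base class for all errors raised by infoflow."""


class DataError(InfoFlowError):
    """Input data is malformed: non-numeric cells, non-finite values, missing entries."""


class InsufficientDataError(DataError):
    """Fewer observations than the estimator's minimum (N >= d + 2)."""


class ParameterError(InfoFlowError):
    """A parameter is outside its valid range (k, alpha, indices...)."""


class DegenerateSeriesError(InfoFlowError):
    """A series has zero variance; covariances involving it are undefined."""


class SingularCovarianceError(InfoFlowError):
    """The sample covariance matrix is numerically singular (collinear columns)."""


class SingularInformationError(InfoFlowError):
    """The Fisher information matrix is not invertible."""


class UnstableSystemError(InfoFlowError):
    """A linear system has no stationary distribution (unstable drift)."""


class SimulationBlowUpError(InfoFlowError):
    """A simulated trajectory left the finite range (pathological initial state)."""
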