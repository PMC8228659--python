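import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import infoflow as ifl

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: the designed edge set of the six-node benchmark network, 0-based (source, target)
DESIGNED_EDGES = frozenset({(0, 1), (1, 2), (2, 0), (3, 4), (4, 3), (5, 1), (5, 4)})


@pytest.fixture(scope="session")
def var_bench_series():
    """One 10,000-step realisation of the six-node benchmark network (unit noise)."""
    return ifl.simulate_var(ifl.benchmark_var_spec(noise_amp=1.0, N=10_000, seed=1))


@pytest.fixture(scope="session")
def var_bench_result(var_bench_series):
    return ifl.flow_matrix(var_bench_series, ifl.EstimatorConfig(alpha=0.10))


@pytest.fixture(scope="session")
def small_var_series():
    """A short, cheap realisation for structural (non-quantitative) tests."""
    return ifl.simulate_var(ifl.benchmark_var_spec(noise_amp=1.0, N=1_500, seed=3))


def batch_euler(A, noise_amp, dt, n_steps, n_reps, seed, burn_in=0):
    """Vectorised Euler-Maruyama paths for Monte-Carlo property tests.

    Same scheme and per-replicate distribution as simulate_linear_sde, but
    integrates all replicates at once; returns (n_reps, n_steps, d).
    """
    rng = np.random.default_rng(seed)
    d = A.shape[0]
    x = np.zeros((n_reps, d))
    out = np.empty((n_reps, n_steps, d))
    scale = np.asarray(noise_amp) * np.sqrt(dt)
    for n in range(burn_in + n_steps):
        x = x + x @ A.T * dt + rng.standard_normal((n_reps, d)) * scale
        if n >= burn_in:
            out[:, n - burn_in] = x
    return out
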