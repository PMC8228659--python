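import numpy as np
import pytest

import infoflow as ifl
from infoflow.exceptions import ParameterError, SingularCovarianceError
from infoflow.series import CovarianceStructure


def _cov_of(values, k=1, dt=1.0):
    ts = ifl.TimeSeriesSet(values, dt, tuple(f"c{i}" for i in range(values.shape[1])))
    return ts, ifl.covariance_structure(ts, ifl.derive_series(ts, k))


class TestFitDrift:
    def test_ou_drift_recovered(self):
        """1-D Ornstein-Uhlenbeck: the drift coefficient -1 is recovered.

        A single 100-time-unit path determines the drift only to ~15%
        (about sqrt(2 tau / T_total)), so the check averages replicates.
        """
        coeffs, gs = [], []
        for seed in (5, 9, 10, 11, 12):
            ts = ifl.simulate_linear_sde(
                ifl.SDESpec(A=[[-1.0]], f=[0.0], noise_amp=[1.0], dt=0.001,
                            N=100_000, seed=seed, burn_in=5_000)
            )
            cov = ifl.covariance_structure(ts, ifl.derive_series(ts, 1))
            fit = ifl.fit_drift(cov, 0)
            coeffs.append(fit.coeffs[0])
            gs.append(fit.noise_g)
        assert np.mean(coeffs) == pytest.approx(-1.0, rel=0.10)
        assert np.mean(gs) == pytest.approx(1.0, rel=0.10)

    def test_white_noise_cross_coefficients_null(self):
        """Independent columns: every cross coefficient is within 3 SE of zero."""
        rng = np.random.default_rng(21)
        ts, cov = _cov_of(rng.normal(size=(5_000, 3)))
        fit = ifl.fit_drift(cov, 0)
        fisher = ifl.fisher_information(ts.values[: cov.n_eff],
                                        ifl.derive_series(ts, 1).values[:, 0], fit)
        for j in (1, 2):
            se = np.sqrt(fisher.cov_theta[1 + j, 1 + j])
            assert abs(fit.coeffs[j]) < 3.0 * se

    def test_residual_sum_matches_direct_loop(self):
        """The covariance-expansion form of Q equals the explicit residual sum."""
        rng = np.random.default_rng(5)
        ts, cov = _cov_of(rng.normal(size=(300, 3)), k=2, dt=0.5)
        xdot = ifl.derive_series(ts, 2)
        for target in range(3):
            fit = ifl.fit_drift(cov, target)
            resid = xdot.values[:, target] - (
                fit.intercept + ts.values[: cov.n_eff] @ fit.coeffs
            )
            assert fit.residual_q == pytest.approx(float(resid @ resid), rel=1e-9)

    def test_singular_covariance_raises(self):
        x = np.random.default_rng(0).normal(size=100)
        vals = np.column_stack([x, 2.0 * x, np.random.default_rng(1).normal(size=100)])
        _, cov = _cov_of(vals)
        with pytest.raises(SingularCovarianceError):
            ifl.fit_drift(cov, 0)


class TestFlowPair:
    def test_bivariate_reduction_machine_precision(self, small_var_series):
        """For d=2 the multivariate estimator reduces to the closed-form
        two-series formula to 1e-12 relative, both directions."""
        two = small_var_series.values[:, [0, 1]]
        ts = ifl.TimeSeriesSet(two, 1.0, ("a", "b"))
        cov = ifl.covariance_structure(ts, ifl.derive_series(ts, 1))
        t_ba = ifl.flow_pair(cov, ifl.fit_drift(cov, 0), 1)
        t_ab = ifl.flow_pair(cov, ifl.fit_drift(cov, 1), 0)
        b_ba = ifl.bivariate_flow(two[:, 0], two[:, 1], k=1, dt=1.0)
        b_ab = ifl.bivariate_flow(two[:, 1], two[:, 0], k=1, dt=1.0)
        assert t_ba == pytest.approx(b_ba, rel=1e-12)
        assert t_ab == pytest.approx(b_ab, rel=1e-12)

    def test_zero_covariance_zero_flow(self):
        """C_ji = 0 forces the flow estimate to exactly zero."""
        cov = CovarianceStructure(
            C=np.diag([1.0, 2.0]),
            Cdot=np.array([[0.3, -0.4], [0.7, 0.2]]),
            dvar=np.array([1.0, 1.0]),
            xbar=np.zeros(2),
            xdotbar=np.zeros(2),
            n_eff=100,
            k=1,
            dt=1.0,
        )
        fit = ifl.fit_drift(cov, 0)
        assert ifl.flow_pair(cov, fit, 1) == 0.0

    def test_source_equals_target_rejected(self, small_var_series):
        cov = ifl.covariance_structure(
            small_var_series, ifl.derive_series(small_var_series, 1)
        )
        fit = ifl.fit_drift(cov, 2)
        with pytest.raises(ParameterError):
            ifl.flow_pair(cov, fit, 2)

    def test_nil_causality_across_replicates(self):
        """When equation 1 does not involve X2, the 2->1 flow stays within
        3 SE of zero in at least 90% of replicates."""
        A = np.array([[0.5, 0.0], [0.3, 0.5]])  # X1 drives X2, not vice versa
        hits = 0
        reps = 50
        for s in range(reps):
            ts = ifl.simulate_var(
                ifl.VARSpec(A=A, intercept=[0.0, 0.0], noise_amp=[1.0, 1.0],
                            N=1_000, seed=100 + s)
            )
            res = ifl.flow_matrix(ts)
            hits += abs(res.T[1, 0]) <= 3.0 * res.se_T[1, 0]
        assert hits >= 0.9 * reps


class TestInvariances:
    def test_uniform_rescaling_leaves_flows_unchanged(self, small_var_series):
        res0 = ifl.flow_matrix(small_var_series)
        scaled = ifl.TimeSeriesSet(
            small_var_series.values * 37.5, 1.0, small_var_series.names
        )
        res1 = ifl.flow_matrix(scaled)
        np.testing.assert_allclose(res1.T, res0.T, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(res1.tau, res0.tau, rtol=1e-9, atol=1e-12)

    def test_scaling_one_conditioning_column(self, small_var_series):
        """Scaling a non-target column leaves flows into any other target unchanged."""
        res0 = ifl.flow_matrix(small_var_series)
        vals = small_var_series.values.copy()
        vals[:, 2] *= -4.0
        res1 = ifl.flow_matrix(
            ifl.TimeSeriesSet(vals, 1.0, small_var_series.names)
        )
        keep = [i for i in range(6) if i != 2]
        np.testing.assert_allclose(
            res1.T[np.ix_(keep, keep)], res0.T[np.ix_(keep, keep)], rtol=1e-8
        )

    def test_invariance_under_conditioning_recombination(self, small_var_series):
        """T[2->1] is invariant under an invertible linear recombination of
        the remaining columns (estimator analogue of the invariance theorem)."""
        vals = small_var_series.values
        res0 = ifl.flow_matrix(small_var_series)
        rng = np.random.default_rng(17)
        M = np.eye(4) + 0.3 * rng.normal(size=(4, 4))
        assert abs(np.linalg.det(M)) > 1e-3
        mixed = vals.copy()
        mixed[:, 2:] = vals[:, 2:] @ M.T
        res1 = ifl.flow_matrix(ifl.TimeSeriesSet(mixed, 1.0, small_var_series.names))
        assert res1.T[1, 0] == pytest.approx(res0.T[1, 0], rel=1e-8)
        assert res1.T[0, 1] == pytest.approx(res0.T[0, 1], rel=1e-8)


class TestNormalization:
    def test_budget_and_bounds(self, var_bench_result):
        res = var_bench_result
        d = res.n_vars
        off = ~np.eye(d, dtype=bool)
        assert np.all(np.abs(res.tau[off]) <= 1.0)
        assert np.all(res.dH_noise >= 0.0)
        assert np.all(res.Z >= np.abs(res.dH_self) + res.dH_noise - 1e-12)
        np.testing.assert_array_equal(np.sign(res.T[off]), np.sign(res.tau[off]))

    def test_decomposition_resums(self, small_var_series):
        cov = ifl.covariance_structure(
            small_var_series, ifl.derive_series(small_var_series, 1)
        )
        fit = ifl.fit_drift(cov, 1)
        budget = ifl.entropy_decomposition(cov, fit)
        assert budget.total == pytest.approx(
            budget.self_rate + budget.flows.sum() + budget.noise, abs=1e-14
        )
        assert budget.noise > 0.0

    def test_noise_dominated_tau_small(self):
        """A weak flow into a noise-dominated target has tiny relative weight."""
        z, tau = ifl.normalize_flows(np.array([0.0, 0.01]), self_rate=-0.05, noise=5.0)
        assert z == pytest.approx(5.06)
        assert abs(tau[1]) < 0.002
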