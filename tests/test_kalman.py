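"""Tests for the constrained adaptive EKF: algebra, gating, adaptation, runs."""

import numpy as np
import pytest

import pondwatch as pw
from pondwatch.errors import ConfigError, UndefinedIndexError
from pondwatch.kalman import (
    chi2_threshold,
    default_initial_cov,
    make_filter_state,
)

from conftest import near_zero_params


def _is_psd(P, tol=1e-10):
    return np.all(np.linalg.eigvalsh(0.5 * (P + P.T)) > -tol)


class TestInitNoise:
    def test_measurement_variance(self):
        _, r0 = pw.init_noise(pw.FilterConfig(), meas_std=0.1)
        assert r0 == pytest.approx(0.01)

    def test_process_diagonal(self):
        cfg = pw.FilterConfig(dt=1 / 24, alpha=(0.1,) * 4, xi_max=(5.0,) * 4)
        Q0, _ = pw.init_noise(cfg, meas_std=0.08)
        assert np.allclose(np.diag(Q0), (0.1 * 5.0 / 24) ** 2)
        assert np.diag(Q0)[0] == pytest.approx(4.34e-4, rel=1e-2)

    def test_vanishing_alpha(self):
        cfg = pw.FilterConfig(alpha=(1e-12,) * 4, validate_alpha=False)
        Q0, _ = pw.init_noise(cfg, meas_std=0.08)
        assert np.allclose(np.diag(Q0), 0.0, atol=1e-20)

    def test_alpha_band_validated(self):
        with pytest.raises(ConfigError):
            pw.FilterConfig(alpha=(0.5,) * 4)


class TestPredict:
    def test_frozen_dynamics_identity(self, constant_forcing, typical_state):
        params = near_zero_params()
        cfg = pw.FilterConfig()
        fs = make_filter_state(typical_state, cfg, meas_std=0.08,
                               P0=np.eye(4) * 0.5)
        fs.Q = np.zeros((4, 4))
        out = pw.predict(fs, params, constant_forcing, cfg)
        assert np.allclose(out.x_hat, typical_state, atol=1e-9)
        assert np.allclose(out.P_cov, fs.P_cov, atol=1e-9)

    def test_single_substep_matches_hand_product(self, typical_params,
                                                 constant_forcing, typical_state):
        cfg = pw.FilterConfig(n_substeps=1)
        P0 = np.diag([0.3, 0.2, 0.4, 0.1])
        fs = make_filter_state(typical_state, cfg, meas_std=0.08, P0=P0)
        out = pw.predict(fs, typical_params, constant_forcing, cfg)
        J = pw.jacobian(typical_state, typical_params, 20.0)
        F1 = np.eye(4) + J * cfg.dt
        expected = F1 @ P0 @ F1.T + fs.Q
        assert np.allclose(out.P_cov, 0.5 * (expected + expected.T), atol=1e-12)

    def test_covariance_stays_psd_over_many_steps(self, typical_params, forcing):
        cfg = pw.FilterConfig()
        rng = np.random.default_rng(0)
        fs = make_filter_state([1.5, 0.8, 0.3, 9.0], cfg, meas_std=0.08)
        for k in range(300):
            fs = pw.predict(fs, typical_params, forcing, cfg)
            if k % 10 == 0:
                fs, _ = pw.update(fs, fs.x_hat[3] + rng.normal(0, 0.1))
            assert np.allclose(fs.P_cov, fs.P_cov.T)
            assert _is_psd(fs.P_cov)


class TestUpdate:
    def _state(self, var_o=1.0, R=1.0):
        fs = make_filter_state([1.0, 1.0, 1.0, 9.0], pw.FilterConfig(),
                               meas_std=np.sqrt(R),
                               P0=np.diag([1.0, 1.0, 1.0, var_o]))
        return fs

    def test_zero_innovation_keeps_state(self):
        fs = self._state()
        out, rec = pw.update(fs, 9.0)
        assert rec.Y == 0.0
        assert np.allclose(out.x_hat, fs.x_hat)

    def test_scalar_kalman_algebra(self):
        fs = self._state(var_o=1.0, R=1.0)
        out, rec = pw.update(fs, 10.0)
        assert rec.S == pytest.approx(2.0)
        assert out.x_hat[3] == pytest.approx(9.5)   # gain 0.5
        assert out.P_cov[3, 3] == pytest.approx(0.5)

    def test_no_information_limit(self):
        fs = self._state(var_o=1.0, R=1e12)
        out, _ = pw.update(fs, 15.0)
        assert np.allclose(out.x_hat, fs.x_hat, atol=1e-6)

    def test_posterior_variance_never_grows(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            var_o, R = rng.uniform(0.01, 5.0, 2)
            fs = self._state(var_o=var_o, R=R)
            out, _ = pw.update(fs, rng.normal(9.0, 1.0))
            assert out.P_cov[3, 3] <= fs.P_cov[3, 3] + 1e-12


class TestConstraintsAndGate:
    def test_projection_cases(self):
        cfg = pw.FilterConfig(o_min=0.0, o_max=20.0)
        assert np.allclose(
            pw.project_constraints([-0.1, 0.5, 0.2, 25.0], cfg), [0, 0.5, 0.2, 20]
        )
        assert np.allclose(
            pw.project_constraints([1.0, 0.5, 0.2, 9.0], cfg), [1, 0.5, 0.2, 9]
        )
        assert np.allclose(
            pw.project_constraints([-1, -1, -1, -5], cfg), [0, 0, 0, 0]
        )

    def test_chi2_gate_decisions(self):
        cfg = pw.FilterConfig(chi2_level=0.90)
        assert chi2_threshold(cfg, 1) == pytest.approx(2.7055, abs=1e-3)
        d2, ok = pw.anomaly_gate(0.0, 1.0, cfg)
        assert d2 == 0.0 and ok
        d2, ok = pw.anomaly_gate(1.0, 1.0, cfg)
        assert d2 == pytest.approx(1.0) and ok
        d2, ok = pw.anomaly_gate(2.0, 1.0, cfg)
        assert d2 == pytest.approx(4.0) and not ok

    def test_physical_anomaly_flags(self):
        cfg = pw.FilterConfig(o_max=20.0)
        flagged, v = pw.check_physical_anomaly([1, 1, 1, 25.0], cfg)
        assert flagged and "O > Omax" in v
        flagged, _ = pw.check_physical_anomaly([1, 1, 1, 9.0], cfg)
        assert not flagged
        flagged, v = pw.check_physical_anomaly([1, 1, -0.01, 9.0], cfg)
        assert flagged and "F < 0" in v


class TestAdaptNoise:
    def _consistency_run(self, true_R_schedule, n=2000, seed=0):
        """Static DO-only toy problem with known noise levels."""
        cfg = pw.FilterConfig(adapt_lambda=0.05)
        params = near_zero_params()
        forcing = pw.TemperatureForcing(T_mean=20.0, amplitude=0.0)
        rng = np.random.default_rng(seed)
        fs = make_filter_state([1, 1, 1, 10.0], cfg, meas_std=0.1,
                               P0=np.diag([1e-6] * 3 + [0.01]))
        Rs = []
        for k in range(n):
            fs = pw.predict(fs, params, forcing, cfg)
            s_prior = fs.P_cov[3, 3] + fs.R
            z = 10.0 + rng.normal(0, true_R_schedule(k))
            fs, _ = pw.update(fs, z)
            fs = pw.adapt_noise(fs, cfg, S_prior=s_prior)
            Rs.append(fs.R)
        return np.array(Rs)

    def test_consistent_noise_keeps_R_close(self):
        Rs = self._consistency_run(lambda k: 0.1)
        # long-run estimate near true variance 0.01 (5% band)
        assert abs(np.mean(Rs[-500:]) - 0.01) / 0.01 < 0.05

    def test_noise_step_increases_R(self):
        Rs = self._consistency_run(lambda k: 0.1 if k < 1000 else 0.2)
        assert np.mean(Rs[1500:]) > np.mean(Rs[500:1000]) * 2.0

    def test_R_floor_is_respected(self):
        cfg = pw.FilterConfig()
        Rs = self._consistency_run(lambda k: 0.1)
        assert np.all(Rs >= cfg.r_floor)


class TestRunFilter:
    def test_perfect_model_self_consistency(self, typical_params, forcing,
                                            typical_state):
        """Exact model, no noise, exact start: estimates track truth closely."""
        sched = pw.SamplingSchedule(duration_d=30.0)
        noise = pw.NoiseSpec(meas_std_do=0.0, process_std=0.0)
        sim = pw.simulate_truth(typical_params, forcing, noise, typical_state, sched)
        recs = [(t, o) for t, o in zip(sim.times, sim.states[:, 3])]
        cfg = pw.FilterConfig(adapt=False)
        run = pw.run_filter(recs, typical_params, forcing, cfg, typical_state,
                            P0=np.diag([1e-8] * 4), meas_std=0.08)
        assert np.max(np.abs(run.x_post - sim.states)) < 1e-3

    def test_error_reduction_band_vs_open_loop(self):
        """Mean state-RMSE reduction vs no-update propagation sits in a band
        containing 35-60% over seeded replicates of the bloom scenario."""
        reds = []
        for seed in range(20):
            params, forcing, noise, x0, sched = pw.reference_scenario(
                duration_d=30.0, seed=seed)
            sim = pw.simulate_truth(params, forcing, noise, x0, sched)
            recs = pw.sample_measurements(sim, None, noise, sched)
            cfg = pw.FilterConfig()
            run = pw.run_filter(recs, params, forcing, cfg, x0,
                                P0=np.diag([0.01, 0.01, 0.01, 0.0064]),
                                meas_std=noise.meas_std_do)
            ol = pw.open_loop(recs, params, forcing, cfg, x0)
            reds.append(1 - pw.rmse(sim.states, run.x_post)
                        / pw.rmse(sim.states, ol))
        mean_red = float(np.mean(reds)) * 100
        assert mean_red >= 35.0
        assert mean_red <= 90.0  # sanity: band containing the expected 35-60%

    def test_spike_is_gated_and_estimate_stays_put(self):
        params, forcing, noise, x0, sched = pw.reference_scenario(
            duration_d=5.0, seed=2)
        sim = pw.simulate_truth(params, forcing, noise, x0, sched)
        recs = pw.sample_measurements(sim, None, noise, sched)
        k = 60
        spiked = list(recs)
        r = spiked[k]
        spiked[k] = pw.MeasurementRecord(
            timestamp=r.timestamp, do_mg_l=r.do_mg_l + 10.0, temp_c=r.temp_c)
        cfg = pw.FilterConfig()
        run = pw.run_filter(spiked, params, forcing, cfg, x0,
                            P0=np.diag([0.01, 0.01, 0.01, 0.0064]),
                            meas_std=noise.meas_std_do)
        assert not run.accepted[k]
        jump = abs(run.x_post[k, 3] - run.x_post[k - 1, 3])
        assert jump < 0.5

    def test_weak_observability_of_fish(self):
        """Posterior std of F stays above P and Z under a field-style start."""
        params, forcing, noise, x0, sched = pw.reference_scenario(
            duration_d=30.0, seed=0)
        sim = pw.simulate_truth(params, forcing, noise, x0, sched)
        recs = pw.sample_measurements(sim, None, noise, sched)
        cfg = pw.FilterConfig()
        run = pw.run_filter(recs, params, forcing, cfg, x0,
                            meas_std=noise.meas_std_do)  # default P0
        stds = np.sqrt(run.P_diag[len(run.times) // 2:]).mean(axis=0)
        assert stds[2] > stds[0]
        assert stds[2] > stds[1]

    def test_residual_calibration(self):
        """One-step DO residuals behave like a Gaussian: ~68%/95% coverage."""
        params, forcing, noise, x0, sched = pw.reference_scenario(
            duration_d=30.0, seed=0)
        sim = pw.simulate_truth(params, forcing, noise, x0, sched)
        recs = pw.sample_measurements(sim, None, noise, sched)
        run = pw.run_filter(recs, params, forcing, pw.FilterConfig(), x0,
                            P0=np.diag([0.01, 0.01, 0.01, 0.0064]),
                            meas_std=noise.meas_std_do)
        res = run.innovation[np.isfinite(run.innovation)]
        assert np.sqrt(np.mean(res**2)) <= 0.15
        mu, sd = res.mean(), res.std()
        within1 = np.mean(np.abs(res - mu) <= sd) * 100
        within2 = np.mean(np.abs(res - mu) <= 2 * sd) * 100
        assert within1 == pytest.approx(68.3, abs=5.0)
        assert within2 == pytest.approx(95.5, abs=5.0)

    def test_empty_records_error(self, typical_params, forcing, typical_state):
        with pytest.raises(ConfigError):
            pw.run_filter([], typical_params, forcing, pw.FilterConfig(),
                          typical_state)


class TestLinearKalmanEquivalence:
    def test_matches_textbook_filter_on_linear_dynamics(self, constant_forcing):
        """With trophic interactions off the dynamics are linear and the EKF
        must agree with a plain linear Kalman filter built from explicitly
        computed transition matrices."""
        eps = 1e-12
        params = pw.EcosystemParams(
            rP=eps, K=5.0, gZ=eps, gF=eps, hP=0.5, hZ=0.3, eZ=eps, eF=eps,
            mP=0.1, mZ=0.08, mF=0.05, aP=0.3, bR=0.1, k2=0.15, Osat_base=10.0)
        cfg = pw.FilterConfig(adapt=False, n_substeps=4)
        x0 = np.array([1.5, 0.8, 0.3, 9.0])
        P0 = np.diag([0.4, 0.3, 0.2, 0.1])
        meas = [9.1, 9.3, 8.8, 9.0, 9.2, 9.4, 8.9, 9.1]

        # --- independent linear KF ---
        J = pw.jacobian(x0, params, 20.0)  # constant for linear dynamics
        h = cfg.dt / cfg.n_substeps
        # covariance transition: first-order factor per substep
        F_cov = np.linalg.matrix_power(np.eye(4) + J * h, cfg.n_substeps)
        # mean transition: RK4 of a linear+affine system per substep
        M = (np.eye(4) + J * h + (J @ J) * h**2 / 2
             + (J @ J @ J) * h**3 / 6 + (J @ J @ J @ J) * h**4 / 24)
        osat = 10.0
        c = np.array([0.0, 0.0, 0.0, params.k2 * osat])
        # affine response of one RK4 substep to the constant forcing c
        B = (np.eye(4) * h + J * h**2 / 2 + (J @ J) * h**3 / 6
             + (J @ J @ J) * h**4 / 24)
        H = np.array([0.0, 0.0, 0.0, 1.0])
        R = 0.08**2
        Q0, _ = pw.init_noise(cfg, 0.08)
        x, P = x0.copy(), P0.copy()
        ref_states = []
        for z in meas:
            for _ in range(cfg.n_substeps):
                x = M @ x + B @ c
            P = F_cov @ P @ F_cov.T + Q0
            P = 0.5 * (P + P.T)
            S = H @ P @ H + R
            K = P @ H / S
            x = x + K * (z - H @ x)
            P = (np.eye(4) - np.outer(K, H)) @ P
            P = 0.5 * (P + P.T)
            ref_states.append(x.copy())

        # --- EKF under test ---
        fs = make_filter_state(x0, cfg, meas_std=0.08, P0=P0)
        ekf_states = []
        for z in meas:
            fs = pw.predict(fs, params, constant_forcing, cfg)
            fs, _ = pw.update(fs, z)
            ekf_states.append(fs.x_hat.copy())

        assert np.max(np.abs(np.array(ref_states) - np.array(ekf_states))) < 1e-8


class TestDiagnostics:
    def test_rmse_cases(self):
        a = np.zeros((5, 4))
        assert pw.rmse(a, a) == 0.0
        b = a.copy()
        b[:, 2] += 0.3  # constant offset on one component
        assert pw.rmse(a, b) == pytest.approx(0.3)
        assert pw.rmse(np.array([0.0, 0.0]), np.array([1.0, -1.0])) == 1.0
        with pytest.raises(ConfigError):
            pw.rmse(np.zeros((3, 4)), np.zeros((4, 4)))

    def test_stability_index_cases(self):
        const = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        assert pw.stability_index(const) == pytest.approx(1.0)
        # one component constant at 2, one with mean 4 and std 1
        t = np.arange(1000)
        comp2 = 4.0 + np.sqrt(2.0) * np.sin(2 * np.pi * t / 50)  # std ~1
        traj = np.column_stack([np.full_like(comp2, 2.0), comp2])
        si = pw.stability_index(traj)
        assert si == pytest.approx(0.875, abs=0.002)
        # larger fluctuations => strictly lower index
        bigger = np.column_stack([traj[:, 0], 4.0 + 2 * (comp2 - 4.0)])
        assert pw.stability_index(bigger) < si

    def test_stability_index_guard(self):
        traj = np.column_stack([np.zeros(10), np.ones(10)])
        with pytest.raises(UndefinedIndexError):
            pw.stability_index(traj)
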