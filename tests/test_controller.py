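"""State-space controller: input matrix, plant, Kalman, targets, PI loop."""

import numpy as np
import pytest

from tubesteer.controller import (
    ClosedLoopScenario,
    ControlInput,
    ControllerConfig,
    ControllerError,
    StateEstimate,
    TargetRef,
    apply_input,
    closed_loop_simulate,
    input_matrix,
    kalman_step,
    pi_control,
    plant_step,
    select_target,
    step_target_schedule,
)
from tubesteer.flow_model import (
    InterfacePositions,
    LinearPlantModel,
    StreamFlows,
)


def feasible_start(model: LinearPlantModel, tfr: float) -> StreamFlows:
    """Initial flows putting the interfaces at (0.2, 0.4) for this plant."""
    f3 = 0.2 / model.b3
    f2 = 0.2 / model.b2
    return StreamFlows(tfr - f2 - f3, f2, f3)


class TestInputMatrix:
    def test_equal_coefficients_give_diagonal(self):
        B = input_matrix(LinearPlantModel(b2=0.1, b3=0.1))
        assert np.allclose(B, 0.1 * np.eye(2))

    def test_unequal_coefficients(self):
        B = input_matrix(LinearPlantModel(b2=0.08, b3=0.12))
        assert np.allclose(B, [[0.12, 0.0], [0.04, 0.08]])

    def test_matrix_matches_static_flow_map(self):
        """One plant tick equals re-evaluating the static linear map with
        the updated flows, for arbitrary inputs."""
        rng = np.random.default_rng(0)
        model = LinearPlantModel(b2=0.07, b3=0.11)
        B = input_matrix(model)
        f = StreamFlows(3.0, 4.0, 3.0)
        for _ in range(20):
            u = ControlInput(*rng.uniform(-0.5, 0.5, 2))
            try:
                f_new = apply_input(f, u)
            except Exception:
                continue
            x = model.positions(f).as_array()
            x_step = x + B @ u.as_array()
            x_static = model.positions(f_new).as_array()
            assert np.allclose(x_step, x_static, atol=1e-12)


class TestPlantStep:
    B = np.array([[0.1, 0.0], [0.0, 0.1]])

    def test_zero_input_zero_noise_is_identity(self):
        x = InterfacePositions(0.3, 0.6)
        out = plant_step(x, ControlInput(0, 0), self.B, noise_sd=0.0)
        assert out.as_array() == pytest.approx([0.3, 0.6])

    def test_matrix_multiply(self):
        x = InterfacePositions(0.3, 0.6)
        out = plant_step(x, ControlInput(1.0, 0.0), self.B, noise_sd=0.0)
        assert out.as_array() == pytest.approx([0.4, 0.6])

    def test_noise_standard_deviation(self):
        rng = np.random.default_rng(3)
        x = InterfacePositions(0.5, 0.5)
        increments = []
        for _ in range(1000):
            out = plant_step(x, ControlInput(0, 0), self.B, noise_sd=0.01,
                             rng=rng)
            increments.extend(out.as_array() - 0.5)
        assert np.std(increments) == pytest.approx(0.01, rel=0.10)

    def test_constraint_violating_step_rejected(self):
        x = InterfacePositions(0.3, 0.6)
        with pytest.raises(ControllerError):
            plant_step(x, ControlInput(5.0, 0.0), self.B,
                       f_current=StreamFlows(3, 4, 3))


class TestKalman:
    config = ControllerConfig()

    def test_perfect_observation_limit(self):
        cfg = ControllerConfig(r_obs=1e-12)
        est = StateEstimate([0.2, 0.8], np.eye(2))
        y = InterfacePositions(0.4, 0.6)
        out = kalman_step(est, ControlInput(0, 0), y, np.eye(2) * 0.1, cfg)
        assert out.xhat == pytest.approx([0.4, 0.6], abs=1e-6)

    def test_repeated_observations_converge_and_cov_shrinks(self):
        cfg = ControllerConfig(q=1e-12)
        est = StateEstimate([0.0, 1.0], 0.1 * np.eye(2))
        y = InterfacePositions(0.35, 0.65)
        traces = []
        for _ in range(100):
            est = kalman_step(est, ControlInput(0, 0), y, np.eye(2) * 0.1, cfg)
            traces.append(np.trace(est.cov))
        assert est.xhat == pytest.approx([0.35, 0.65], abs=1e-3)
        assert all(b <= a + 1e-15 for a, b in zip(traces, traces[1:]))

    def test_matches_independent_scalar_filter_when_decoupled(self):
        """With a diagonal B the 2-D filter equals two scalar Kalman
        filters run independently on each coordinate."""
        cfg = ControllerConfig(q=1e-4, r_obs=1e-3)
        B = np.diag([0.1, 0.1])
        rng = np.random.default_rng(8)
        est = StateEstimate([0.3, 0.7], 0.05 * np.eye(2))
        xs = np.array([0.3, 0.7])
        p_s = np.array([0.05, 0.05])
        for _ in range(50):
            u = ControlInput(*rng.uniform(-0.2, 0.2, 2))
            yv = np.sort(rng.uniform(0, 1, 2))
            y = InterfacePositions(*yv)
            est = kalman_step(est, u, y, B, cfg)
            # scalar reference on each decoupled coordinate
            for i in range(2):
                xp = xs[i] + B[i, i] * u.as_array()[i]
                pp = p_s[i] + cfg.q
                k = pp / (pp + cfg.r_obs)
                xs[i] = xp + k * (yv[i] - xp)
                p_s[i] = (1 - k) * pp
            assert est.xhat == pytest.approx(xs, abs=1e-10)
            assert np.diag(est.cov) == pytest.approx(p_s, abs=1e-10)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ControllerError):
            StateEstimate([0.5, 0.5], [[1.0, 2.0], [2.0, 1.0]])


class TestTargetSelection:
    def test_growing_toward_stream1_wall_activates_m2(self):
        t = select_target(0.6, 30.0, InterfacePositions(0.3, 0.7))
        assert t.active == 2
        assert t.r2 == pytest.approx(0.6)
        assert t.r3 == pytest.approx(0.3)  # dummy holds the observation

    def test_growing_toward_stream3_wall_activates_m3(self):
        t = select_target(0.5, -20.0, InterfacePositions(0.2, 0.8))
        assert t.active == 3
        assert t.r3 == pytest.approx(0.5)
        assert t.r2 == pytest.approx(0.8)

    def test_parallel_growth_activates_nearest_interface(self):
        t = select_target(0.45, 0.0, InterfacePositions(0.4, 0.9))
        assert t.active == 3

    def test_tip_outside_channel_rejected(self):
        with pytest.raises(ControllerError):
            select_target(1.2, 0.0, InterfacePositions(0.3, 0.7))


class TestPIControl:
    config = ControllerConfig()

    def test_zero_error_zero_integral_gives_zero_input(self):
        target = TargetRef(0.3, 0.6, active=3)
        u, integral = pi_control(np.zeros(2), np.zeros(2), self.config,
                                 StreamFlows(4, 3, 3), target)
        assert u.f23 == 0.0 and u.f12 == 0.0
        assert np.all(integral == 0)

    def test_sign_moves_active_interface_toward_target(self):
        """Positive error on m3 must move m3 up through the plant."""
        model = LinearPlantModel(b2=0.1, b3=0.1)
        B = input_matrix(model)
        target = TargetRef(0.5, 0.6, active=3)
        e = np.array([0.2, 0.0])
        f = StreamFlows(4, 3, 3)
        u, _ = pi_control(e, np.zeros(2), self.config, f, target)
        x = InterfacePositions(0.3, 0.6)
        x_new = plant_step(x, u, B, noise_sd=0.0)
        assert x_new.m3 > x.m3

    def test_projection_keeps_flows_feasible(self):
        target = TargetRef(0.99, 0.995, active=3)
        f = StreamFlows(9.9, 0.05, 0.05)
        u, _ = pi_control(np.array([10.0, 0.0]), np.zeros(2),
                          ControllerConfig(kp=100.0), f, target)
        f_new = apply_input(f, u)
        arr = f_new.as_array()
        assert np.all(arr >= -1e-12) and np.all(arr <= 10 + 1e-12)
        assert arr.sum() == pytest.approx(10.0, abs=1e-9)

    def test_integral_frozen_when_clipped(self):
        target = TargetRef(0.99, 0.995, active=3)
        f = StreamFlows(9.9, 0.05, 0.05)
        _, integral = pi_control(np.array([10.0, 0.0]), np.zeros(2),
                                 ControllerConfig(kp=100.0), f, target)
        assert integral[0] == 0.0  # anti-windup: no accumulation


class TestClosedLoop:
    def test_noiseless_step_settles_and_stays(self):
        model = LinearPlantModel(b2=0.1, b3=0.1)
        scen = ClosedLoopScenario(
            model=model, initial_flows=feasible_start(model, 10.0),
            n_ticks=60, target_schedule=step_target_schedule(0.5, 0.7, 3))
        log = closed_loop_simulate(scen, seed=1)
        err = np.abs(log.frame.m3_true - 0.5)
        settle = np.argmax((err < scen.config.settle_tol).to_numpy())
        assert settle <= 15
        assert np.all(err.to_numpy()[settle:] < scen.config.settle_tol)

    def test_flow_conservation_is_exact(self):
        model = LinearPlantModel(b2=0.1, b3=0.1, process_noise_sd=0.005)
        scen = ClosedLoopScenario(
            model=model, initial_flows=feasible_start(model, 10.0),
            n_ticks=500, obs_noise_sd=0.01,
            target_schedule=step_target_schedule(0.5, 0.7, 3))
        log = closed_loop_simulate(scen, seed=2)
        assert log.conservation_exact
        sums = log.frame[["f1", "f2", "f3"]].sum(axis=1).to_numpy()
        assert np.all(sums == 10.0)  # bit-exact, not approximately

    def test_zero_gains_freeze_the_plant(self):
        model = LinearPlantModel(b2=0.1, b3=0.1)
        scen = ClosedLoopScenario(
            model=model, initial_flows=feasible_start(model, 10.0),
            n_ticks=30, config=ControllerConfig(kp=0.0, ki=0.0),
            target_schedule=step_target_schedule(0.9, 0.95, 3))
        log = closed_loop_simulate(scen, seed=0)
        assert np.all(log.frame.u_f23 == 0.0)
        assert np.all(log.frame.u_f12 == 0.0)
        assert log.frame.m3_true.nunique() == 1

    def test_noisy_steady_state_error_bounded(self):
        """Steady-state mean error stays within twice the observation
        noise, averaged over seeded repetitions."""
        model = LinearPlantModel(b2=0.1, b3=0.1)
        errs = []
        for seed in range(20):
            scen = ClosedLoopScenario(
                model=model, initial_flows=feasible_start(model, 10.0),
                n_ticks=80, obs_noise_sd=0.01,
                target_schedule=step_target_schedule(0.5, 0.7, 3))
            log = closed_loop_simulate(scen, seed=seed)
            errs.append(np.abs(log.frame.m3_true.iloc[40:] - 0.5).mean())
        assert np.mean(errs) < 0.02

    def test_innovation_whiteness_on_long_noisy_run(self):
        model = LinearPlantModel(b2=0.1, b3=0.1, process_noise_sd=0.002)
        scen = ClosedLoopScenario(
            model=model, initial_flows=feasible_start(model, 10.0),
            n_ticks=5000, obs_noise_sd=0.01,
            target_schedule=step_target_schedule(0.5, 0.7, 3))
        log = closed_loop_simulate(scen, seed=7)
        resid = (log.frame.m3_obs - log.frame.m3_hat).to_numpy()[200:]
        rho = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(rho) < 0.1

    def test_infeasible_initial_flows_raise_setup_error(self):
        model = LinearPlantModel(b2=0.2, b3=0.2)
        with pytest.raises(ControllerError):
            closed_loop_simulate(ClosedLoopScenario(
                model=model, initial_flows=StreamFlows(2, 4, 4),
                target_schedule=step_target_schedule(0.5, 0.7, 3)), seed=0)

    def test_reproducible_given_seed(self):
        model = LinearPlantModel(b2=0.1, b3=0.1, process_noise_sd=0.003)
        scen = ClosedLoopScenario(
            model=model, initial_flows=feasible_start(model, 10.0),
            n_ticks=100, obs_noise_sd=0.01,
            target_schedule=step_target_schedule(0.5, 0.7, 3))
        a = closed_loop_simulate(scen, seed=5).frame
        b = closed_loop_simulate(scen, seed=5).frame
        assert a.equals(b)
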