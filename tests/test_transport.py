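"""Reduced-order flow + Ca2+ transport solver and calibration procedures."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import erf

from tubesteer.flow_model import StreamFlows, ideal_interface_positions
from tubesteer.transport import (
    ChannelGeometry,
    ConcentrationField,
    FluorCalibration,
    GridSpec,
    TransportError,
    TransportParams,
    analytic_coflow_profile,
    depth_averaged_velocity,
    estimate_diffusion_coefficient,
    fit_fluorescence_calibration,
    signal_to_concentration,
    solve_steady_transport,
    sweep_tip_offset,
    tip_concentration_difference,
)

# compact geometry for module tests: same physics, quicker solves
GEOM = ChannelGeometry(width=300.0, length=600.0,
                       tip_streamwise_position=450.0)
PARAMS = TransportParams(tfr=6.0, inlet_concentrations=(20.0, 0.13, 20.0))
FLOWS = StreamFlows(2.0, 2.0, 2.0)


def mean_velocity(geom, params):
    return params.tfr * 1e-9 / 60.0 / (geom.width * 1e-6 * geom.height * 1e-6)


class TestVelocity:
    def test_flux_and_centreline_plug(self):
        vel = depth_averaged_velocity(GEOM, PARAMS)
        assert vel.volumetric_flux(0) == pytest.approx(PARAMS.tfr, rel=1e-3)
        assert vel.volumetric_flux(-1) == pytest.approx(PARAMS.tfr, rel=1e-3)
        u_mid = vel.u_center[vel.u_center.shape[0] // 2,
                             vel.u_center.shape[1] // 2]
        assert u_mid == pytest.approx(mean_velocity(GEOM, PARAMS), rel=1e-3)

    def test_zero_flow_gives_zero_field(self):
        params = TransportParams(tfr=0.0)
        vel = depth_averaged_velocity(GEOM, params)
        assert np.all(vel.u_face == 0.0) and np.all(vel.v_face == 0.0)

    def test_symmetric_obstacle_gives_symmetric_field(self):
        vel = depth_averaged_velocity(GEOM, PARAMS,
                                      tube_lateral_um=GEOM.width / 2)
        u = vel.u_center
        assert np.max(np.abs(u - u[:, ::-1])) < 1e-10 * np.max(np.abs(u))

    def test_obstacle_slows_the_strip(self):
        vel = depth_averaged_velocity(GEOM, PARAMS,
                                      tube_lateral_um=GEOM.width / 2)
        i = int(GEOM.tip_streamwise_position / vel.grid.dx) - 2
        j = vel.obstacle.shape[1] // 2
        assert vel.u_center[i, j] < 0.3 * mean_velocity(GEOM, PARAMS)

    def test_obstacle_wider_than_channel_rejected(self):
        with pytest.raises(TransportError):
            ChannelGeometry(width=10.0, tube_diameter=17.0)


class TestAnalyticProfile:
    def test_midpoint_at_interface(self):
        c = analytic_coflow_profile(1e-4, 1e-3, 0.01, 1.3e-9, 0.13, 20.0, 1e-4)
        assert c == pytest.approx((0.13 + 20.0) / 2)

    def test_far_field_reaches_inlet_values(self):
        c_lo = analytic_coflow_profile(0.0, 1e-3, 0.01, 1.3e-9, 0.13, 20.0,
                                       3e-4)
        c_hi = analytic_coflow_profile(6e-4, 1e-3, 0.01, 1.3e-9, 0.13, 20.0,
                                       3e-4)
        assert c_lo == pytest.approx(0.13, abs=1e-6)
        assert c_hi == pytest.approx(20.0, abs=1e-6)

    def test_zero_downstream_distance_rejected(self):
        with pytest.raises(TransportError):
            analytic_coflow_profile(0.0, 0.0, 0.01, 1.3e-9, 0.13, 20.0, 1e-4)


class TestSteadyTransport:
    def test_uniform_inlets_give_uniform_field(self):
        params = TransportParams(tfr=6.0, inlet_concentrations=(5.0, 5.0, 5.0))
        fld = solve_steady_transport(GEOM, params, FLOWS)
        assert np.nanmax(np.abs(fld.values - 5.0)) < 1e-10

    def test_solver_matches_analytic_erf_profile(self):
        """No-obstacle solve vs the two-interface erf superposition."""
        fld = solve_steady_transport(GEOM, PARAMS, FLOWS)
        pos = ideal_interface_positions(FLOWS)
        u = mean_velocity(GEOM, PARAMS)
        x_st = GEOM.tip_streamwise_position
        x_cell = fld.x_centers[int(x_st / fld.grid.dx - 0.5)] * 1e-6
        y = fld.y_centers * 1e-6
        w = np.sqrt(4 * PARAMS.diffusion_coefficient * x_cell / u)
        c3, c2 = 20.0, 0.13
        ana = c3 + (c2 - c3) * 0.5 * (
            erf((y - pos.m3 * GEOM.width * 1e-6) / w)
            - erf((y - pos.m2 * GEOM.width * 1e-6) / w))
        prof = fld.profile_at(x_st)["concentration_mM"].to_numpy()
        scaled_err = np.max(np.abs(prof - ana)) / (20.0 - 0.13)
        assert scaled_err <= 1e-2

    def test_error_decreases_under_grid_refinement(self):
        """Lateral refinement reduces the solver-vs-erf error (order >= 1
        behaviour on the dominant lateral discretisation)."""
        errs = []
        for dy in (8.0, 4.0, 2.0):
            fld = solve_steady_transport(GEOM, PARAMS, FLOWS,
                                         grid=GridSpec(dx=10.0, dy=dy))
            pos = ideal_interface_positions(FLOWS)
            u = mean_velocity(GEOM, PARAMS)
            x_st = GEOM.tip_streamwise_position
            x_cell = fld.x_centers[int(x_st / fld.grid.dx - 0.5)] * 1e-6
            y = fld.y_centers * 1e-6
            w = np.sqrt(4 * PARAMS.diffusion_coefficient * x_cell / u)
            ana = 20.0 + (0.13 - 20.0) * 0.5 * (
                erf((y - pos.m3 * GEOM.width * 1e-6) / w)
                - erf((y - pos.m2 * GEOM.width * 1e-6) / w))
            prof = fld.profile_at(x_st)["concentration_mM"].to_numpy()
            errs.append(np.max(np.abs(prof - ana)))
        assert errs[2] < errs[1] < errs[0]

    def test_mass_conservation_flux_audit(self):
        fld = solve_steady_transport(GEOM, PARAMS, FLOWS,
                                     tube_lateral_um=GEOM.width / 2)
        inlet, outlet = fld.flux_audit()
        assert abs(inlet - outlet) / inlet < 1e-3

    def test_maximum_principle(self):
        fld = solve_steady_transport(GEOM, PARAMS, FLOWS,
                                     tube_lateral_um=GEOM.width / 2)
        assert np.nanmin(fld.values) >= 0.13 - 1e-9
        assert np.nanmax(fld.values) <= 20.0 + 1e-9

    def test_residual_reported_below_tolerance(self):
        fld = solve_steady_transport(GEOM, PARAMS, FLOWS)
        assert fld.residual < 1e-5


class TestTipDifference:
    def test_uniform_field_gives_zero(self):
        params = TransportParams(tfr=6.0, inlet_concentrations=(5.0, 5.0, 5.0))
        fld = solve_steady_transport(GEOM, params, FLOWS,
                                     tube_lateral_um=GEOM.width / 2)
        assert tip_concentration_difference(fld, GEOM.width / 2) == \
            pytest.approx(0.0, abs=1e-9)

    def test_linear_gradient_recovers_slope_times_diameter(self):
        vel = depth_averaged_velocity(GEOM, PARAMS)
        grid = vel.grid
        ny = vel.obstacle.shape[1]
        slope = 0.05  # mM per µm
        y = (np.arange(ny) + 0.5) * grid.dy
        values = np.tile(slope * y, (vel.obstacle.shape[0], 1))
        fld = ConcentrationField(values, vel.obstacle, grid, GEOM, 0.0, vel)
        dc = tip_concentration_difference(fld, GEOM.width / 2)
        assert dc == pytest.approx(slope * GEOM.tube_diameter, rel=0.01)

    def test_tip_near_wall_rejected(self):
        fld = solve_steady_transport(GEOM, PARAMS, FLOWS)
        with pytest.raises(TransportError):
            tip_concentration_difference(fld, 2.0)


class TestOffsetSweep:
    """Two-stream symmetric scenario: interface at the channel centre."""

    params = TransportParams(tfr=6.0, inlet_concentrations=(20.0, 0.13, 0.13))
    flows = StreamFlows(3.0, 0.0, 3.0)  # m3 = m2 = 0.5: one interface

    def test_bell_is_symmetric_and_peaks_at_zero(self):
        offsets = [-30.0, -15.0, 0.0, 15.0, 30.0]
        df = sweep_tip_offset(GEOM, self.params, self.flows, offsets,
                              interface="m2")
        dc = df["dc_mM"].to_numpy()
        assert np.argmax(np.abs(dc)) == 2  # peak at zero offset
        for i, j in ((0, 4), (1, 3)):
            assert abs(abs(dc[i]) - abs(dc[j])) <= 0.05 * abs(dc[2])

    def test_offset_outside_channel_rejected(self):
        with pytest.raises(TransportError):
            sweep_tip_offset(GEOM, self.params, self.flows, [200.0])


class TestFluorCalibration:
    def test_exact_line_recovered(self):
        cal_true = FluorCalibration(slope=40.0, intercept=120.0)
        conc = np.array([0.002, 0.05, 1.0])
        signals = cal_true.forward(conc)
        fit = fit_fluorescence_calibration(conc, signals)
        assert fit.slope == pytest.approx(40.0, abs=1e-9)
        assert fit.intercept == pytest.approx(120.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_signals_recover_slope_within_5pct(self):
        rng = np.random.default_rng(9)
        cal_true = FluorCalibration(slope=40.0, intercept=120.0)
        conc = np.array([0.002, 0.01, 0.05, 0.2, 1.0])
        signals = cal_true.forward(conc)
        signals = signals * (1 + rng.normal(0, 0.02, signals.shape))
        fit = fit_fluorescence_calibration(conc, signals)
        assert fit.slope == pytest.approx(40.0, rel=0.05)

    def test_out_of_range_concentration_flagged(self):
        cal_true = FluorCalibration(slope=40.0, intercept=120.0)
        conc = np.array([0.002, 1.0, 5.0])  # 5 mM beyond the linear range
        with pytest.warns(UserWarning):
            fit_fluorescence_calibration(conc, cal_true.forward(conc))

    def test_single_concentration_rejected(self):
        with pytest.raises(TransportError):
            fit_fluorescence_calibration([0.05, 0.05], [10.0, 10.0])


class TestSignalInversion:
    cal = FluorCalibration(slope=40.0, intercept=120.0)

    def test_round_trip_through_calibration(self):
        conc = np.array([0.005, 0.005, 0.2, 0.2, 0.9])
        baseline = np.full(5, 7.0)
        apparent = self.cal.forward(conc) + baseline
        out, n_masked = signal_to_concentration(apparent, baseline, self.cal)
        assert n_masked == 0
        assert np.allclose(out.compressed(), conc, atol=1e-9)

    def test_baseline_equal_to_apparent_masks_everything(self):
        sig = np.full(4, 50.0)
        with pytest.warns(UserWarning):
            out, n_masked = signal_to_concentration(sig, sig, self.cal)
        assert n_masked == 4
        assert out.mask.all()

    def test_saturating_signal_masked(self):
        baseline = np.zeros(2)
        apparent = np.array([self.cal.forward(0.5),
                             self.cal.forward(1.0) + 50.0])
        out, n_masked = signal_to_concentration(apparent, baseline, self.cal)
        assert n_masked == 1
        assert bool(out.mask[1]) and not bool(out.mask[0])


class TestDiffusionCoefficient:
    def _measured_profile(self, d_true):
        """Profile synthesized from the analytic erf solution — an
        independent route from the solver used for scoring."""
        u = mean_velocity(GEOM, PARAMS)
        pos = ideal_interface_positions(FLOWS)
        y = np.arange(1.0, GEOM.width, 2.0)
        c3, c2 = 20.0, 0.13
        w = np.sqrt(4 * d_true * GEOM.tip_streamwise_position * 1e-6 / u)
        conc = c3 + (c2 - c3) * 0.5 * (
            erf((y - pos.m3 * GEOM.width) * 1e-6 / w)
            - erf((y - pos.m2 * GEOM.width) * 1e-6 / w))
        return pd.DataFrame({"position_um": y, "concentration_mM": conc})

    def test_selects_generating_value(self):
        prof = self._measured_profile(1.3e-9)
        best, table = estimate_diffusion_coefficient(
            prof, GEOM, PARAMS, FLOWS, [7e-9, 1.3e-9])
        assert best == pytest.approx(1.3e-9)
        assert len(table) == 2 and table["D_m2_s"].is_monotonic_increasing

    def test_single_candidate_returned_with_score(self):
        prof = self._measured_profile(1.3e-9)
        best, table = estimate_diffusion_coefficient(
            prof, GEOM, PARAMS, FLOWS, [2e-9])
        assert best == pytest.approx(2e-9)
        assert table.loc[0, "sse"] > 0

    def test_no_candidates_rejected(self):
        with pytest.raises(TransportError):
            estimate_diffusion_coefficient(
                self._measured_profile(1.3e-9), GEOM, PARAMS, FLOWS, [])
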