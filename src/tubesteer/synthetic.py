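"""Synthetic microscopy sequences with known ground truth.

Renders fluorescence or brightfield time-lapse frames of the main
channel — three co-flowing streams whose Fluo-3 intensity follows a
log-linear Ca2+ calibration, erf-smoothed diffusion-blurred interfaces,
a growing capsule-shaped pollen tube, and Gaussian + Poisson camera
noise — together with a per-frame ground-truth log.  A simple virtual
pollen tube turns away from out-of-tolerance Ca2+ at its flanks with a
saturating (tanh) response; it is a test harness for the trackers and
the closed-loop controller, not a biological model.

Conventions match the trackers: image row 0 is the stream-1 wall
(controller coordinate m = 1), the bottom row is the stream-3 wall
(m = 0), and columns run streamwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import erf

from .controller import ControllerConfig, TargetRef
from .flow_model import InterfacePositions, LinearPlantModel, StreamFlows
from .tracking_fluor import Frame
from .transport import ChannelGeometry, FluorCalibration

__all__ = [
    "TubeState",
    "VirtualTubeParams",
    "Scene",
    "GroundTruthLog",
    "SyntheticError",
    "default_calibration",
    "render_frame",
    "sense_tip_difference",
    "virtual_tube_step",
    "SequenceScenario",
    "generate_sequence",
    "SteeringResult",
    "steering_experiment",
    "generate_calibration_sweep",
    "write_sequence",
]


class SyntheticError(ValueError):
    """Invalid scene or scenario."""


def default_calibration() -> FluorCalibration:
    """Fluo-3-style log-linear calibration spanning an 8-bit-ish range."""
    return FluorCalibration(slope=40.0, intercept=120.0)


@dataclass(frozen=True)
class TubeState:
    """Virtual pollen tube in channel coordinates (µm).

    ``anchor`` is where the tube enters the view, ``tip`` its growing
    end; ``direction_deg`` is 0° downstream (+x), positive toward the
    stream-1 wall (+y); width is the lily-tube average 17 µm.
    """

    anchor: tuple[float, float]
    tip: tuple[float, float]
    direction_deg: float = 0.0
    width_um: float = 17.0
    bend_points: tuple[tuple[float, float], ...] = ()

    @property
    def segments(self) -> np.ndarray:
        pts = [self.anchor, *self.bend_points, self.tip]
        return np.asarray(pts, dtype=float)


@dataclass(frozen=True)
class VirtualTubeParams:
    """Chemotropic response parameters of the virtual tube.

    The tolerated Ca2+ band (default 0.05-0.13 mM) is the range the
    tubes accept without turning; outside it the heading rotates away
    from the unfavourable side at kappa·tanh(|Δc|/c0) degrees per
    minute, clamped at ``max_turn_deg_per_min``.
    """

    growth_rate_um_min: float = 12.0
    turn_gain_deg_per_min: float = 60.0
    saturation_mM: float = 1.0
    max_turn_deg_per_min: float = 80.0
    tolerated_band_mM: tuple[float, float] = (0.05, 0.13)
    angle_noise_deg: float = 0.0
    escape_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.growth_rate_um_min <= 0 or self.max_turn_deg_per_min <= 0:
            raise SyntheticError("growth rate and max turn must be > 0")


@dataclass
class Scene:
    """Static description of one rendered scenario."""

    geom: ChannelGeometry = field(default_factory=ChannelGeometry)
    pixel_size_um: float = 2.0
    view_length_um: float = 600.0
    concentrations_mM: tuple[float, float, float] = (20.0, 0.13, 20.0)
    interfaces: InterfacePositions = field(
        default_factory=lambda: InterfacePositions(0.3335, 0.6665))
    interface_blur_um: float = 20.0
    tube: TubeState | None = None
    gaussian_noise_sd: float = 2.0
    poisson_scale: float = 2.0  # photons per intensity count; 0 disables
    modality: str = "fluorescence"
    calibration: FluorCalibration = field(default_factory=default_calibration)
    tube_brightness: float = 230.0

    def __post_init__(self) -> None:
        if self.modality not in ("fluorescence", "brightfield"):
            raise SyntheticError("modality must be fluorescence or brightfield")
        if self.tube is not None and self.tube.width_um >= self.geom.width:
            raise SyntheticError("tube wider than channel")

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.geom.width / self.pixel_size_um)),
                int(round(self.view_length_um / self.pixel_size_um)))

    # --- coordinate transforms -----------------------------------------
    def to_px(self, xy_um: tuple[float, float]) -> tuple[float, float]:
        """Channel (x, y) µm -> image (row, col) px."""
        x, y = xy_um
        row = (self.geom.width - y) / self.pixel_size_um - 0.5
        col = x / self.pixel_size_um - 0.5
        return row, col

    def wall_rows(self) -> tuple[float, float]:
        """(top, bottom) wall rows bounding the channel in the image."""
        return (-0.5, self.shape[0] - 0.5)

    def interface_rows(self) -> tuple[float, float]:
        """Image rows of the m2 (upper) and m3 (lower) interfaces."""
        r2 = self.to_px((0.0, self.interfaces.m2 * self.geom.width))[0]
        r3 = self.to_px((0.0, self.interfaces.m3 * self.geom.width))[0]
        return r2, r3

    def expected_plateau_sd(self, intensity: float) -> float:
        """Predicted noise sd on a flat plateau of the given intensity."""
        var = self.gaussian_noise_sd**2
        if self.poisson_scale > 0:
            var += intensity / self.poisson_scale
        return float(np.sqrt(var))


def intensity_ridge_rows(scene: Scene) -> tuple[float, float]:
    """Image rows of the two fluorescence intensity-gradient ridges.

    Because the Fluo-3 response is log-linear in Ca2+, the observable
    intensity edge of an interface peaks where |c'/c| is largest —
    shifted toward the dim stream relative to the concentration
    midpoint.  This is the correct oracle for intensity-based interface
    tracking; the geometric (concentration-midpoint) rows are logged
    separately.  Returned as (upper ridge row, lower ridge row) with
    sub-pixel quadratic interpolation.
    """
    h = scene.shape[0]
    y_um = scene.geom.width - (np.arange(h) + 0.5) * scene.pixel_size_um
    c1, c2, c3 = scene.concentrations_mM
    y3 = scene.interfaces.m3 * scene.geom.width
    y2 = scene.interfaces.m2 * scene.geom.width
    w = max(scene.interface_blur_um, 1e-6)
    conc = (c3 + (c2 - c3) * 0.5 * (1 + erf((y_um - y3) / w))
            + (c1 - c2) * 0.5 * (1 + erf((y_um - y2) / w)))
    profile = np.asarray(scene.calibration.forward(np.maximum(conc, 1e-9)))
    # evaluate the ridge at the measurement scale (detectors smooth at
    # ~1.5 px before differentiating)
    from scipy.ndimage import gaussian_filter1d
    gm = np.abs(np.gradient(gaussian_filter1d(profile, 1.5)))
    r2_row, r3_row = scene.interface_rows()
    rows = []
    for target in (r2_row, r3_row):
        lo = max(int(target) - 25, 1)
        hi = min(int(target) + 26, h - 1)
        seg = gm[lo:hi]
        k = int(np.argmax(seg)) + lo
        # quadratic sub-pixel refinement around the peak
        denom = gm[k - 1] - 2 * gm[k] + gm[k + 1]
        delta = 0.5 * (gm[k - 1] - gm[k + 1]) / denom if denom != 0 else 0.0
        rows.append(k + float(np.clip(delta, -1, 1)))
    return rows[0], rows[1]


def _capsule_distance(shape: tuple[int, int], scene: Scene,
                      tube: TubeState) -> np.ndarray:
    """Distance (px) from each pixel to the tube's polyline centreline."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    pts = np.stack([rows, cols], axis=-1)
    dmin = np.full(shape, np.inf)
    seg = [scene.to_px(tuple(p)) for p in tube.segments]
    for a, b in zip(seg[:-1], seg[1:]):
        a, b = np.asarray(a), np.asarray(b)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(pts - a, axis=-1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d = np.linalg.norm(pts - proj, axis=-1)
        dmin = np.minimum(dmin, d)
    return dmin


def render_frame(scene: Scene, rng: np.random.Generator | None = None,
                 timestamp_s: float = 0.0) -> Frame:
    """Render one frame of the scene; seeded and bit-reproducible.

    Fluorescence: per-stream plateau intensities are the calibration
    forward values of the stream Ca2+ concentrations, with erf-smoothed
    interfaces of the stated blur width and a bright capsule tube.
    Brightfield: flat background with faint intensity ridges at the
    interfaces (refractive-index visibility) and a dark-halo tube edge.
    Gaussian and Poisson noise are applied when an rng is given.
    """
    h, wcols = scene.shape
    y_um = scene.geom.width - (np.arange(h) + 0.5) * scene.pixel_size_um
    c1, c2, c3 = scene.concentrations_mM
    y3 = scene.interfaces.m3 * scene.geom.width
    y2 = scene.interfaces.m2 * scene.geom.width
    w = max(scene.interface_blur_um, 1e-6)
    conc = (c3 + (c2 - c3) * 0.5 * (1 + erf((y_um - y3) / w))
            + (c1 - c2) * 0.5 * (1 + erf((y_um - y2) / w)))
    if scene.modality == "fluorescence":
        profile = np.asarray(scene.calibration.forward(np.maximum(conc, 1e-9)))
        img = np.tile(profile[:, None], (1, wcols))
        if scene.tube is not None:
            dist = _capsule_distance((h, wcols), scene, scene.tube)
            r = scene.tube.width_um / 2 / scene.pixel_size_um
            soft = 0.5 * (1 + np.tanh((r - dist) / 0.75))
            img = img + (scene.tube_brightness - img) * soft
    else:
        img = np.full((h, wcols), 128.0)
        for y_if in (y3, y2):
            row_if = scene.to_px((0.0, y_if))[0]
            rr = np.arange(h)[:, None]
            img += 12.0 * np.exp(-0.5 * ((rr - row_if) / 1.5) ** 2)
        if scene.tube is not None:
            dist = _capsule_distance((h, wcols), scene, scene.tube)
            r = scene.tube.width_um / 2 / scene.pixel_size_um
            img -= 90.0 * np.exp(-0.5 * ((dist - r) / 1.2) ** 2)  # dark halo
            img += 12.0 * (dist < r - 1.5)  # slightly bright interior
    img = np.clip(img, 0.0, None)
    if rng is not None:
        if scene.poisson_scale > 0:
            img = rng.poisson(img * scene.poisson_scale) / scene.poisson_scale
        if scene.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, scene.gaussian_noise_sd, img.shape)
        img = np.clip(img, 0.0, None)
    return Frame(img, pixel_size_um=scene.pixel_size_um,
                 timestamp_s=timestamp_s)


# ---------------------------------------------------------------------------
# virtual tube
# ---------------------------------------------------------------------------


def sense_tip_difference(
    tip_y_um: float,
    interface_y_um: float,
    c_near_mM: float,
    c_far_mM: float,
    blur_um: float,
    tube_width_um: float = 17.0,
) -> tuple[float, float, float]:
    """Flank concentrations and their difference at the tube tip.

    Evaluates the erf interface profile at tip ± half a tube width;
    returns (c at +y flank, c at -y flank, Δc) with Δc positive toward
    +y (the stream-1 wall).  ``c_far`` is the concentration on the +y
    side of the interface, ``c_near`` on the -y side.
    """
    w = max(blur_um, 1e-9)
    half = tube_width_um / 2

    def c_at(y):
        return c_near_mM + (c_far_mM - c_near_mM) * 0.5 * (
            1 + erf((y - interface_y_um) / w))

    hi = c_at(tip_y_um + half)
    lo = c_at(tip_y_um - half)
    return float(hi), float(lo), float(hi - lo)


def virtual_tube_step(
    tube: TubeState,
    flank_hi_mM: float,
    flank_lo_mM: float,
    params: VirtualTubeParams,
    dt_s: float,
    rng: np.random.Generator | None = None,
) -> TubeState:
    """Advance and possibly turn the virtual tube over one tick.

    The tip advances growth_rate·dt along the heading.  If either flank
    concentration leaves the tolerated band, the heading rotates away
    from the unfavourable side by min(max_turn, kappa·tanh(|Δc|/c0))·dt
    plus optional angular noise; inside the band it grows straight.
    """
    if dt_s <= 0:
        raise SyntheticError("dt must be > 0")
    dt_min = dt_s / 60.0
    lo_band, hi_band = params.tolerated_band_mM
    dc = flank_hi_mM - flank_lo_mM

    def badness(c: float) -> float:
        return max(c - hi_band, 0.0) / hi_band + max(lo_band - c, 0.0) / lo_band

    bad_hi, bad_lo = badness(flank_hi_mM), badness(flank_lo_mM)
    turn = 0.0
    if max(bad_hi, bad_lo) > 0:
        rate = min(params.max_turn_deg_per_min,
                   params.turn_gain_deg_per_min
                   * np.tanh(abs(dc) / params.saturation_mM))
        # rotate away from the worse side: -y wallward turn is negative
        sign = -1.0 if bad_hi >= bad_lo else 1.0
        # stop once the heading already points away by the escape angle
        heading = (tube.direction_deg + 180.0) % 360.0 - 180.0
        if sign * heading >= params.escape_angle_deg:
            rate = 0.0
        turn = sign * rate * dt_min
    if rng is not None and params.angle_noise_deg > 0:
        turn += rng.normal(0.0, params.angle_noise_deg) * np.sqrt(dt_min)
    new_dir = tube.direction_deg + turn
    step = params.growth_rate_um_min * dt_min
    ang = np.deg2rad(new_dir)
    tip = (tube.tip[0] + step * np.cos(ang), tube.tip[1] + step * np.sin(ang))
    bends = tube.bend_points
    if abs(turn) > 1e-9:
        bends = (*bends, tube.tip)
    return replace(tube, tip=tip, direction_deg=new_dir, bend_points=bends)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthLog:
    """Per-frame truth for a rendered sequence (the test oracle)."""

    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def tip_px(self) -> np.ndarray:
        return np.array([r["tip_px"] for r in self.records])

    def directions_deg(self) -> np.ndarray:
        return np.array([r["direction_deg"] for r in self.records])

    def interface_rows(self) -> np.ndarray:
        return np.array([r["interface_rows"] for r in self.records])

    def to_json_lines(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


@dataclass
class SequenceScenario:
    """Recipe for a synthetic sequence.

    ``mode`` is "open_loop" (interfaces fixed by the scene flows) or
    "closed_loop" (the controller steers the active interface to the
    virtual tube tip each tick, with observation noise in normalized
    units).
    """

    scene: Scene
    n_frames: int = 50
    dt_s: float = 3.0
    mode: str = "open_loop"
    tube_params: VirtualTubeParams = field(default_factory=VirtualTubeParams)
    grow_tube: bool = False
    tfr: float = 10.0
    controller_config: ControllerConfig = field(default_factory=ControllerConfig)
    obs_noise_sd: float = 0.0


def generate_sequence(scenario: SequenceScenario, seed: int = 0
                      ) -> tuple[list[Frame], GroundTruthLog]:
    """Render a frame sequence with its self-consistent ground truth.

    Every frame is rendered at the logged interface positions and tube
    state; identical seeds give identical sequences.
    """
    if scenario.mode not in ("open_loop", "closed_loop"):
        raise SyntheticError(f"unknown mode {scenario.mode!r}")
    scene = scenario.scene
    rng = np.random.default_rng(seed)
    frames: list[Frame] = []
    log = GroundTruthLog()
    model = LinearPlantModel.ideal(scenario.tfr)
    from .flow_model import flows_from_targets
    flows = flows_from_targets(scene.interfaces, scenario.tfr)
    from .controller import StateEstimate, input_matrix, kalman_step, pi_control
    est = StateEstimate(scene.interfaces.as_array().copy(), 0.01 * np.eye(2))
    integral = np.zeros(2)
    bmat = input_matrix(model)
    tube = scene.tube
    width = scene.geom.width

    for k in range(scenario.n_frames):
        t_s = k * scenario.dt_s
        pos = model.positions(flows)
        scene_k = replace(scene, interfaces=pos, tube=tube)
        frame = render_frame(scene_k, rng=rng, timestamp_s=t_s)
        frames.append(frame)
        rec = {
            "frame": k, "t_s": t_s,
            "interfaces": [pos.m3, pos.m2],
            "interface_rows": list(scene_k.interface_rows()),
            "flows": [flows.f1, flows.f2, flows.f3],
        }
        if scene.modality == "fluorescence":
            rec["interface_ridge_rows"] = list(intensity_ridge_rows(scene_k))
        dc = 0.0
        if tube is not None:
            # the observable tip is the capsule apex, half a width beyond
            # the centreline endpoint
            ang = np.deg2rad(tube.direction_deg)
            apex = (tube.tip[0] + tube.width_um / 2 * np.cos(ang),
                    tube.tip[1] + tube.width_um / 2 * np.sin(ang))
            tip_px = scene_k.to_px(apex)
            rec.update({"tip_px": list(tip_px),
                        "direction_deg": tube.direction_deg % 360.0,
                        "tip_um": list(apex)})
            c1, c2, _c3 = scene.concentrations_mM
            hi, lo, dc = sense_tip_difference(
                tube.tip[1], pos.m2 * width, c2, c1,
                scene.interface_blur_um, tube.width_um)
            rec["dc_mM"] = dc
            rec["tip_interface_um"] = tube.tip[1] - pos.m2 * width
        log.records.append(rec)

        # advance state for the next frame
        if tube is not None and (scenario.grow_tube
                                 or scenario.mode == "closed_loop"):
            hi, lo, _ = sense_tip_difference(
                tube.tip[1], model.positions(flows).m2 * width,
                scene.concentrations_mM[1], scene.concentrations_mM[0],
                scene.interface_blur_um, tube.width_um)
            tube = virtual_tube_step(tube, hi, lo, scenario.tube_params,
                                     scenario.dt_s, rng=rng)
        if scenario.mode == "closed_loop" and tube is not None:
            y_arr = pos.as_array()
            if scenario.obs_noise_sd > 0:
                y_arr = np.clip(y_arr + rng.normal(
                    0, scenario.obs_noise_sd, 2), 0, 1)
            y = InterfacePositions(*sorted(y_arr))
            from .controller import ControlInput
            est = kalman_step(est, ControlInput(0.0, 0.0), y, bmat,
                              scenario.controller_config)
            tip_m = float(np.clip(tube.tip[1] / width, 0.0, 1.0))
            target = TargetRef(r3=y.m3, r2=tip_m, active=2)
            e = target.as_array() - est.xhat
            u, integral = pi_control(e, integral,
                                     scenario.controller_config, flows, target)
            from .controller import apply_input
            flows = apply_input(flows, u, tfr=scenario.tfr)
    return frames, log


@dataclass
class SteeringResult:
    """Outcome of one state-space steering run (no rendering)."""

    t_s: np.ndarray
    tip_um: np.ndarray  # (n, 2) channel (x, y)
    direction_deg: np.ndarray
    interface_um: np.ndarray  # m2 interface lateral position
    dc_mM: np.ndarray

    def trajectory(self):
        """Tip track as an image-frame Trajectory for the analysis module."""
        from .analysis import Trajectory

        rows = -self.tip_um[:, 1]  # +y (stream-1-ward) maps to -row
        cols = self.tip_um[:, 0]
        return Trajectory(self.t_s, np.column_stack([rows, cols]),
                          pixel_size_um=1.0)


def steering_experiment(
    c_side_mM: float,
    control: str = "auto",
    seed: int = 0,
    n_ticks: int = 160,
    dt_s: float = 3.0,
    c_mid_mM: float = 0.13,
    tfr: float = 10.0,
    channel_width_um: float = 500.0,
    interface_blur_um: float = 20.0,
    tube_params: VirtualTubeParams | None = None,
    config: ControllerConfig | None = None,
    obs_noise_sd: float = 0.01,
    manual_lag_ticks: int = 5,
    manual_jitter_sd: float = 0.02,
) -> SteeringResult:
    """One steering experiment of the digital twin, state-space only.

    A virtual tube starts in the middle stream growing obliquely toward
    the m2 interface; the interface is steered to the tip either by the
    closed-loop controller (``control="auto"``: Kalman + constrained PI
    on the flows) or by an emulated human operator (``"manual"``: the
    same target but applied with a first-order lag of
    ``manual_lag_ticks`` and positional jitter, the variability the
    automation removes).  The tube senses the flank Ca2+ difference
    through the erf interface profile and turns per its response law.
    """
    if control not in ("auto", "manual"):
        raise SyntheticError("control must be 'auto' or 'manual'")
    rng = np.random.default_rng(seed)
    tube_params = tube_params or VirtualTubeParams(angle_noise_deg=0.5)
    config = config or ControllerConfig()
    from .controller import (ControlInput, StateEstimate, apply_input,
                             input_matrix, kalman_step, pi_control)
    from .flow_model import flows_from_targets

    model = LinearPlantModel.ideal(tfr)
    bmat = input_matrix(model)
    width = channel_width_um
    # tube enters mid-stream, heading 20 deg toward the stream-1 wall
    tube = TubeState(anchor=(0.0, 0.55 * width), tip=(60.0, 0.55 * width),
                     direction_deg=20.0)
    start = InterfacePositions(0.3335, 0.82)
    flows = flows_from_targets(start, tfr)
    est = StateEstimate(start.as_array().copy(), 0.01 * np.eye(2))
    integral = np.zeros(2)
    manual_pos = start.m2
    t, tips, dirs, ifs, dcs = [], [], [], [], []
    pos = start
    for k in range(n_ticks):
        if control == "auto":
            y_arr = np.clip(pos.as_array()
                            + rng.normal(0, obs_noise_sd, 2), 0, 1)
            y = InterfacePositions(*sorted(y_arr))
            est = kalman_step(est, ControlInput(0.0, 0.0), y, bmat, config)
            tip_m = float(np.clip(tube.tip[1] / width, 0.0, 1.0))
            target = TargetRef(r3=y.m3, r2=tip_m, active=2)
            e = target.as_array() - est.xhat
            u, integral = pi_control(e, integral, config, flows, target)
            flows = apply_input(flows, u, tfr=tfr)
            pos = model.positions(flows)
        else:
            # human operator: lagged pursuit of the tip plus jitter
            tip_m = float(np.clip(tube.tip[1] / width, 0.0, 1.0))
            manual_pos += (tip_m - manual_pos) / max(manual_lag_ticks, 1)
            m2 = float(np.clip(manual_pos + rng.normal(0, manual_jitter_sd),
                               0, 1))
            pos = InterfacePositions(min(start.m3, m2), max(start.m3, m2))
        hi, lo, dc = sense_tip_difference(
            tube.tip[1], pos.m2 * width, c_mid_mM, c_side_mM,
            interface_blur_um)
        t.append(k * dt_s)
        tips.append(tube.tip)
        dirs.append(tube.direction_deg)
        ifs.append(pos.m2 * width)
        dcs.append(dc)
        tube = virtual_tube_step(tube, hi, lo, tube_params, dt_s, rng=rng)
    return SteeringResult(np.asarray(t), np.asarray(tips), np.asarray(dirs),
                          np.asarray(ifs), np.asarray(dcs))


def generate_calibration_sweep(
    model: LinearPlantModel,
    n_points: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    tfr: float = 10.0,
) -> list[tuple[StreamFlows, InterfacePositions]]:
    """Random feasible flow sweep with observed positions from the model."""
    if n_points < 2:
        raise SyntheticError("sweep needs n_points >= 2")
    rng = np.random.default_rng(seed)
    sweep = []
    for _ in range(n_points):
        # rejection-sample the flow simplex for settings whose positions
        # stay inside the channel under this plant model
        for _try in range(200):
            parts = rng.dirichlet([2.0, 2.0, 2.0]) * tfr
            f = StreamFlows(parts[0], parts[1], parts[2])
            if model.b3 * f.f3 + model.b2 * f.f2 <= 1.0:
                break
        else:
            raise SyntheticError("could not sample feasible flows")
        pos = model.positions(f)
        m = pos.as_array()
        if noise_sd > 0:
            m = np.clip(m + rng.normal(0, noise_sd, 2), 0, 1)
        lo, hi = sorted(m)
        sweep.append((f, InterfacePositions(lo, hi)))
    return sweep


def write_sequence(frames: list[Frame], log: GroundTruthLog,
                   out_dir: str | Path, stem: str = "sequence") -> None:
    """Write frames as a multi-page TIFF plus truth as JSON lines."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.image for f in frames]).astype(np.float32)
    tifffile.imwrite(out / f"{stem}.tif", stack, photometric="minisblack")
    log.to_json_lines(out / f"{stem}_truth.jsonl")
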