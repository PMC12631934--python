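"""Reduced-order steady flow and Ca2+ transport in the main channel.

The paper-scale problem is 3-D laminar flow past a cylindrical pollen
tube with advection-diffusion of Ca2+ between co-flowing streams.  This
module solves a depth-averaged 2-D reduction on a uniform streamwise x
lateral grid in two stages:

1. A Stokes-Brinkman solve for the depth-averaged velocity: in-plane
   viscosity plus the Hele-Shaw depth-friction 12µ/h², which gives the
   ~h/sqrt(12) lateral boundary layers that slow the fluid flanking the
   tube.  The tube (diameter 17 µm in a 35 µm-deep channel) blocks only
   part of the depth, so it enters as a high-friction porous strip: its
   friction follows the cubic gap conductance of the open layers above
   and below the tube, not a solid wall.
2. A finite-volume steady advection-diffusion solve (first-order upwind
   convection, central diffusion) on the resulting conservative face
   velocities.  Inside the tube strip the lateral diffusivity is scaled
   by the open depth fraction; this is the depth-averaged analogue of
   Ca2+ bypassing the tube through the gaps, which is what caps the
   right-left concentration difference at the tip.

Concentrations are carried in mM, lengths in µm, flow rates in µL/min
and D in m²/s.  Also here: the fluorescence-calibration fit (signal vs
log10 Ca2+), the baseline-subtraction signal inversion, and candidate
selection for the Ca2+ diffusion coefficient against a measured
cross-channel profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import erf

from .flow_model import StreamFlows, ideal_interface_positions

__all__ = [
    "ChannelGeometry",
    "TransportParams",
    "GridSpec",
    "VelocityField",
    "ConcentrationField",
    "FluorCalibration",
    "TransportError",
    "depth_averaged_velocity",
    "analytic_coflow_profile",
    "solve_steady_transport",
    "tip_concentration_difference",
    "sweep_tip_offset",
    "fit_fluorescence_calibration",
    "signal_to_concentration",
    "estimate_diffusion_coefficient",
]

UL_MIN_TO_M3_S = 1e-9 / 60.0  # µL/min -> m³/s
UM = 1e-6  # µm -> m

#: Fluo-3 linear range in the growth medium, mM (2e-6 to 1e-3 M).
FLUO3_LINEAR_RANGE_MM = (2e-3, 1.0)


class TransportError(ValueError):
    """Invalid geometry, parameters or failed convergence."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Main-channel and pollen-tube geometry, µm.

    The channel is ``length`` long (streamwise x, junction at x = 0) and
    ``width`` wide (lateral y, y = 0 at the stream-3 wall); ``height``
    is the out-of-plane depth.  The tube is a cylinder of
    ``tube_diameter`` whose tip sits ``tip_streamwise_position``
    downstream of the junction, centred at ``tube_center_height`` in
    depth (only used for documentation in the 2-D reduction).
    """

    width: float = 500.0
    height: float = 35.0
    length: float = 1200.0
    tube_diameter: float = 17.0
    tube_length: float = 250.0
    tube_center_height: float = 17.5
    tip_streamwise_position: float = 900.0

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.length, self.tube_diameter,
               self.tube_length, self.tip_streamwise_position) <= 0:
            raise TransportError("all geometry dimensions must be > 0")
        if self.tube_diameter >= self.height:
            raise TransportError("tube diameter must be smaller than channel height")
        if self.tube_diameter >= self.width:
            raise TransportError("obstacle wider than channel")


@dataclass(frozen=True)
class TransportParams:
    """Fluid and species parameters for the steady transport problem.

    ``inlet_concentrations`` are (stream1, stream2, stream3) in mM;
    stream 1 flows along the y = width wall, stream 3 along y = 0.
    """

    diffusion_coefficient: float = 1.3e-9  # m²/s
    tfr: float = 10.0  # µL/min
    inlet_concentrations: tuple[float, float, float] = (20.0, 0.13, 20.0)
    density: float = 1000.0  # kg/m³
    viscosity: float = 1e-3  # Pa·s

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise TransportError("diffusion coefficient must be > 0")
        if any(c < 0 for c in self.inlet_concentrations):
            raise TransportError("inlet concentrations must be >= 0")


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid spacing, µm (default 10 streamwise x 2 lateral)."""

    dx: float = 10.0
    dy: float = 2.0


@dataclass
class VelocityField:
    """Conservative face velocities (m/s) on a staggered uniform grid."""

    u_face: np.ndarray  # (nx+1, ny) streamwise velocity at x-faces
    v_face: np.ndarray  # (nx, ny+1) lateral velocity at y-faces
    obstacle: np.ndarray  # (nx, ny) bool
    grid: GridSpec
    geom: ChannelGeometry

    @property
    def u_center(self) -> np.ndarray:
        return 0.5 * (self.u_face[:-1] + self.u_face[1:])

    @property
    def v_center(self) -> np.ndarray:
        return 0.5 * (self.v_face[:, :-1] + self.v_face[:, 1:])

    def volumetric_flux(self, column: int = 0) -> float:
        """Volumetric flux through an x-face column, µL/min."""
        dy_m = self.grid.dy * UM
        h_m = self.geom.height * UM
        return float(np.sum(self.u_face[column]) * dy_m * h_m / UL_MIN_TO_M3_S)


def _obstacle_mask(geom: ChannelGeometry, grid: GridSpec,
                   tube_lateral_um: float | None) -> np.ndarray:
    nx = int(round(geom.length / grid.dx))
    ny = int(round(geom.width / grid.dy))
    mask = np.zeros((nx, ny), dtype=bool)
    if tube_lateral_um is None:
        return mask
    half = geom.tube_diameter / 2.0
    if not (half < tube_lateral_um < geom.width - half):
        raise TransportError("tube placed outside the channel")
    xc = (np.arange(nx) + 0.5) * grid.dx
    yc = (np.arange(ny) + 0.5) * grid.dy
    in_x = (xc >= geom.tip_streamwise_position - geom.tube_length) & (
        xc <= geom.tip_streamwise_position)
    in_y = np.abs(yc - tube_lateral_um) <= half
    mask[np.ix_(in_x, in_y)] = True
    return mask


def _friction_and_open_fraction(
    geom: ChannelGeometry, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Brinkman friction (µm^-2, µ=1) and open depth fraction.

    Open cells carry the parallel-plate friction 12/h².  Cells in the
    tube strip keep only the gap layers above and below the tube; their
    depth-averaged conductance is the cubic sum of the gap heights, so
    the friction is 12·h/Σg³ and the open depth fraction Σg/h.
    """
    h = geom.height
    g_top = h - geom.tube_center_height - geom.tube_diameter / 2.0
    g_bot = geom.tube_center_height - geom.tube_diameter / 2.0
    g_top, g_bot = max(g_top, 0.0), max(g_bot, 0.0)
    g3 = g_top**3 + g_bot**3
    alpha_open = 12.0 / h**2
    alpha_strip = 12.0 * h / g3 if g3 > 0 else 1e9 * alpha_open
    alpha = np.where(mask, alpha_strip, alpha_open)
    open_frac = np.where(mask, (g_top + g_bot) / h, 1.0)
    return alpha, open_frac


def depth_averaged_velocity(
    geom: ChannelGeometry,
    params: TransportParams,
    tube_lateral_um: float | None = None,
    grid: GridSpec = GridSpec(),
    side_wall_noslip: bool = False,
) -> VelocityField:
    """Depth-averaged steady Stokes-Brinkman velocity field.

    Solves  µ∇²V - α(x,y)·V = ∇p,  ∇·V = 0  on a staggered (MAC) grid
    with a plug inlet, prescribed outlet pressure and impermeable side
    walls; α is the Hele-Shaw depth friction (12µ/h² in the open
    channel, the cubic-gap value inside the tube strip).  The tube is a
    partially-blocking porous strip, not a solid wall: most of the flow
    diverts around it, a small depth-gap fraction leaks through, and
    ~h/sqrt(12) boundary layers of slow fluid form along its flanks.
    Face velocities are returned in m/s with the volumetric flux equal
    to TFR exactly; the lateral profile away from obstacles is plug
    (the depth-averaged limit for a channel much wider than deep), with
    ``side_wall_noslip`` optionally resolving the thin lateral wall
    layers as well.
    """
    mask = _obstacle_mask(geom, grid, tube_lateral_um)
    nx, ny = mask.shape
    if params.tfr == 0:
        return VelocityField(np.zeros((nx + 1, ny)), np.zeros((nx, ny + 1)),
                             mask, grid, geom)
    alpha, _ = _friction_and_open_fraction(geom, mask)
    dx, dy = grid.dx, grid.dy

    n_u = (nx + 1) * ny
    n_v = nx * (ny + 1)
    n_p = nx * ny
    uid = np.arange(n_u).reshape(nx + 1, ny)
    vid = n_u + np.arange(n_v).reshape(nx, ny + 1)
    pid = n_u + n_v + np.arange(n_p).reshape(nx, ny)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(n_u + n_v + n_p)

    def add(r, c, v):
        r, c = np.broadcast_arrays(r, c)
        v = np.broadcast_to(v, r.shape)
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(np.asarray(v, dtype=float).ravel())

    idx2, idy2 = 1.0 / dx**2, 1.0 / dy**2

    # --- u momentum on interior x-faces (i = 1..nx-1) -------------------
    ju = np.arange(ny)[None, :]
    r_u = uid[1:-1, :]
    a_face = 0.5 * (alpha[:-1, :] + alpha[1:, :])  # cells i-1, i
    # lateral boundary ghosts: no-slip u_ghost = -u, free-slip u_ghost = +u
    ydiag_wall = -3.0 * idy2 if side_wall_noslip else -1.0 * idy2
    at_wall = (ju == 0) | (ju == ny - 1)
    diag_u = -2.0 * idx2 - a_face + np.where(at_wall, ydiag_wall, -2.0 * idy2)
    add(r_u, uid[:-2, :], idx2)
    add(r_u, uid[2:, :], idx2)
    add(r_u[:, 1:], uid[1:-1, :-1], idy2)
    add(r_u[:, :-1], uid[1:-1, 1:], idy2)
    add(r_u, r_u, diag_u)
    add(r_u, pid[1:, :], -1.0 / dx)
    add(r_u, pid[:-1, :], 1.0 / dx)

    # inlet faces: plug Dirichlet u = 1
    add(uid[0, :], uid[0, :], np.ones(ny))
    rhs[uid[0, :]] = 1.0
    # outlet faces (i = nx): x-ghost du/dx = 0, outlet pressure 0 half a
    # cell beyond the face
    r_out = uid[nx, :]
    diag_out = -1.0 * idx2 - alpha[-1, :] + np.where(
        at_wall[0], ydiag_wall, -2.0 * idy2)
    add(r_out, uid[nx - 1, :], np.full(ny, idx2))
    add(r_out[1:], uid[nx, :-1], idy2)
    add(r_out[:-1], uid[nx, 1:], idy2)
    add(r_out, r_out, diag_out)
    add(r_out, pid[-1, :], np.full(ny, 2.0 / dx))

    # --- v momentum on interior y-faces (jf = 1..ny-1) ------------------
    iv = np.arange(nx)[:, None]
    r_v = vid[:, 1:-1]
    a_face_v = 0.5 * (alpha[:, :-1] + alpha[:, 1:])
    # x ghosts: inlet plane v = 0 (ghost = -v), outlet dv/dx = 0 (ghost = +v)
    xdiag = np.where(iv == 0, -3.0 * idx2,
                     np.where(iv == nx - 1, -1.0 * idx2, -2.0 * idx2))
    diag_v = -2.0 * idy2 - a_face_v + xdiag
    add(r_v, vid[:, :-2], idy2)
    add(r_v, vid[:, 2:], idy2)
    add(r_v[1:, :], vid[:-1, 1:-1], idx2)
    add(r_v[:-1, :], vid[1:, 1:-1], idx2)
    add(r_v, r_v, diag_v)
    add(r_v, pid[:, 1:], -1.0 / dy)
    add(r_v, pid[:, :-1], 1.0 / dy)
    # wall faces: v = 0
    add(vid[:, 0], vid[:, 0], np.ones(nx))
    add(vid[:, ny], vid[:, ny], np.ones(nx))

    # --- continuity per cell -------------------------------------------
    r_p = pid
    add(r_p, uid[1:, :], 1.0 / dx)
    add(r_p, uid[:-1, :], -1.0 / dx)
    add(r_p, vid[:, 1:], 1.0 / dy)
    add(r_p, vid[:, :-1], -1.0 / dy)

    a_mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(rhs.size, rhs.size))
    sol = spla.spsolve(a_mat.tocsc(), rhs)

    u_face = sol[:n_u].reshape(nx + 1, ny)
    v_face = sol[n_u:n_u + n_v].reshape(nx, ny + 1)
    # scale so the volumetric flux equals TFR exactly (inlet is plug u=1)
    q_now = np.sum(u_face[0]) * (dy * UM) * (geom.height * UM)
    scale = params.tfr * UL_MIN_TO_M3_S / q_now
    return VelocityField(u_face * scale, v_face * scale, mask, grid, geom)


def analytic_coflow_profile(
    lateral_pos: np.ndarray | float,
    downstream_pos: float,
    mean_velocity: float,
    diffusion_coefficient: float,
    c_left: float,
    c_right: float,
    interface_pos: float,
) -> np.ndarray | float:
    """Closed-form co-flow diffusion profile (all lengths in metres).

    c = (cl+cr)/2 + (cr-cl)/2 · erf((y - y_if) / sqrt(4 D x / U)),
    the similarity solution for two uniform streams meeting at x = 0.
    """
    if downstream_pos <= 0:
        raise TransportError("downstream position must be > 0")
    width = np.sqrt(4.0 * diffusion_coefficient * downstream_pos / mean_velocity)
    xi = (np.asarray(lateral_pos, dtype=float) - interface_pos) / width
    out = 0.5 * (c_left + c_right) + 0.5 * (c_right - c_left) * erf(xi)
    return float(out) if np.isscalar(lateral_pos) else out


@dataclass
class ConcentrationField:
    """Steady 2-D Ca2+ field, mM, on the (streamwise x lateral) grid."""

    values: np.ndarray  # (nx, ny); tube-strip cells hold the gap-layer value
    obstacle: np.ndarray
    grid: GridSpec
    geom: ChannelGeometry
    residual: float
    velocity: VelocityField
    tube_lateral_um: float | None = None
    inlet_profile: np.ndarray | None = None

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.values.shape[0]) + 0.5) * self.grid.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.values.shape[1]) + 0.5) * self.grid.dy

    def profile_at(self, x_um: float) -> pd.DataFrame:
        """Cross-channel profile at the station nearest x_um."""
        i = int(np.clip(round(x_um / self.grid.dx - 0.5), 0,
                        self.values.shape[0] - 1))
        return pd.DataFrame(
            {"position_um": self.y_centers, "concentration_mM": self.values[i]})

    def sample(self, x_um: float, y_um: float) -> float:
        """Concentration at the fluid cell nearest (x, y), mM."""
        i = int(np.clip(round(x_um / self.grid.dx - 0.5), 0,
                        self.values.shape[0] - 1))
        j = int(np.clip(round(y_um / self.grid.dy - 0.5), 0,
                        self.values.shape[1] - 1))
        return float(self.values[i, j])

    def flux_audit(self) -> tuple[float, float]:
        """(inlet, outlet) advective species flux, arbitrary common units."""
        dy_m = self.grid.dy * UM
        cin = self.inlet_profile
        inlet = float(np.sum(self.velocity.u_face[0] * cin) * dy_m)
        outlet = float(np.sum(self.velocity.u_face[-1] *
                              np.nan_to_num(self.values[-1])) * dy_m)
        return inlet, outlet

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.x_centers,
                     columns=self.y_centers).to_csv(path)


def _inlet_bands(geom: ChannelGeometry, params: TransportParams,
                 flows: StreamFlows, ny: int, dy: float) -> np.ndarray:
    """Inlet concentration per lateral cell from the ideal stream widths.

    Cells straddling an interface get the area-weighted mean so the
    discrete interface sits exactly at the ideal position.
    """
    pos = ideal_interface_positions(flows)
    c1, c2, c3 = params.inlet_concentrations
    edges = np.arange(ny + 1) * dy / geom.width  # normalised cell edges
    # integral of the band function up to a normalised coordinate s
    def band_integral(s):
        return (c3 * np.clip(s, 0, pos.m3)
                + c2 * np.clip(s - pos.m3, 0, pos.m2 - pos.m3)
                + c1 * np.clip(s - pos.m2, 0, None))
    cell_means = np.diff(band_integral(edges)) / np.diff(edges)
    return cell_means.astype(float)


def solve_steady_transport(
    geom: ChannelGeometry,
    params: TransportParams,
    flows: StreamFlows,
    tube_lateral_um: float | None = None,
    grid: GridSpec = GridSpec(),
    velocity: VelocityField | None = None,
    residual_tol: float = 1e-5,
) -> ConcentrationField:
    """Steady advection-diffusion solve for the Ca2+ field.

    Finite-volume discretisation on the depth-averaged velocity field:
    first-order upwind convection, central diffusion, Dirichlet inlet
    bands set by the ideal stream widths, zero-diffusive-flux outlet and
    impermeable walls/obstacle.  The linear system is solved directly
    and the scaled residual of the returned field is checked against
    ``residual_tol`` (the convergence criterion); failure raises.
    """
    if abs(flows.tfr - params.tfr) > 1e-9 * max(params.tfr, 1.0):
        raise TransportError("flows TFR does not match params.tfr")
    if velocity is None:
        velocity = depth_averaged_velocity(geom, params, tube_lateral_um, grid)
    mask = velocity.obstacle
    nx, ny = mask.shape
    n = nx * ny
    dx_m, dy_m = grid.dx * UM, grid.dy * UM
    d_coef = params.diffusion_coefficient
    cin = _inlet_bands(geom, params, flows, ny, grid.dy)
    _, open_frac = _friction_and_open_fraction(geom, mask)

    cid = np.arange(n).reshape(nx, ny)
    diag = np.zeros(n)
    b = np.zeros(n)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def off_diag(r, c, v):
        rows.append(np.asarray(r).ravel())
        cols.append(np.asarray(c).ravel())
        vals.append(np.asarray(v, dtype=float).ravel())

    # diffusive face conductances: harmonic mean of the per-cell open
    # depth fraction (reduced lateral diffusion through the tube strip)
    def harmonic(a, b_):
        return 2.0 * a * b_ / (a + b_)

    dcx = d_coef * harmonic(open_frac[:-1, :], open_frac[1:, :]) * dy_m / dx_m
    dcy = d_coef * harmonic(open_frac[:, :-1], open_frac[:, 1:]) * dx_m / dy_m
    fx = velocity.u_face * dy_m  # (nx+1, ny) convective face flow
    fy = velocity.v_face * dx_m  # (nx, ny+1)

    # interior x-faces between cells (i-1, j) and (i, j), i = 1..nx-1
    f = fx[1:-1, :]
    w_id, e_id = cid[:-1, :], cid[1:, :]
    np.add.at(diag, e_id.ravel(), (np.maximum(-f, 0) + dcx).ravel())
    np.add.at(diag, w_id.ravel(), (np.maximum(f, 0) + dcx).ravel())
    off_diag(e_id, w_id, -(np.maximum(f, 0) + dcx))
    off_diag(w_id, e_id, -(np.maximum(-f, 0) + dcx))
    # interior y-faces between cells (i, j-1) and (i, j)
    f = fy[:, 1:-1]
    s_id, n_id = cid[:, :-1], cid[:, 1:]
    np.add.at(diag, n_id.ravel(), (np.maximum(-f, 0) + dcy).ravel())
    np.add.at(diag, s_id.ravel(), (np.maximum(f, 0) + dcy).ravel())
    off_diag(n_id, s_id, -(np.maximum(f, 0) + dcy))
    off_diag(s_id, n_id, -(np.maximum(-f, 0) + dcy))
    # inlet: convective inflow (RHS only) + diffusion to Dirichlet ghost
    dcond_in = d_coef * open_frac[0, :] * dy_m / (dx_m / 2)
    diag[cid[0, :]] += dcond_in
    b[cid[0, :]] += (np.maximum(fx[0, :], 0) + dcond_in) * cin
    # outlet: pure convective outflow (zero diffusive flux)
    diag[cid[-1, :]] += np.maximum(fx[-1, :], 0)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    a_mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    c_sol = spla.spsolve(a_mat.tocsc(), b)

    # scaled residual: imbalance relative to the total inlet species flux
    scale = float(np.abs(b).sum()) or 1.0
    residual = float(np.abs(a_mat @ c_sol - b).sum()) / scale
    if not np.isfinite(residual) or residual > residual_tol:
        raise TransportError(
            f"transport solve failed to converge: scaled residual {residual:.3e}")

    return ConcentrationField(c_sol.reshape(nx, ny), mask, grid, geom,
                              residual, velocity, tube_lateral_um,
                              inlet_profile=cin)


def tip_concentration_difference(
    field: ConcentrationField,
    tip_lateral_um: float,
    tube_diameter_um: float | None = None,
) -> float:
    """Right-left Ca2+ difference across the tip, mM.

    Linearly interpolates the cross-channel profile at the tip
    streamwise station at the two flank positions y = tip ± d/2; the
    sign is positive toward the stream-1 wall (y = width).  For a field
    with constant lateral gradient g this returns exactly g·d.
    """
    geom = field.geom
    d = tube_diameter_um if tube_diameter_um is not None else geom.tube_diameter
    half = d / 2.0
    if not (half < tip_lateral_um < geom.width - half):
        raise TransportError("tip within half a tube diameter of a wall")
    prof = field.profile_at(geom.tip_streamwise_position)
    y = prof["position_um"].to_numpy()
    c = prof["concentration_mM"].to_numpy()
    c_hi, c_lo = np.interp([tip_lateral_um + half, tip_lateral_um - half], y, c)
    return float(c_hi - c_lo)


def sweep_tip_offset(
    geom: ChannelGeometry,
    params: TransportParams,
    flows: StreamFlows,
    offsets_um: np.ndarray | list[float],
    grid: GridSpec = GridSpec(),
    interface: str = "m2",
) -> pd.DataFrame:
    """Tip Δc versus lateral tip-to-interface offset (bell curve).

    For each offset the tube (and its tip) is re-positioned at
    interface + offset and the steady field re-solved; returns a tidy
    frame with columns offset_um, dc_mM.
    """
    pos = ideal_interface_positions(flows)
    y_if = (pos.m2 if interface == "m2" else pos.m3) * geom.width
    out = []
    for off in np.asarray(offsets_um, dtype=float):
        y_tube = y_if + off
        half = geom.tube_diameter / 2.0
        if not (half < y_tube < geom.width - half):
            raise TransportError(f"offset {off} places the tube outside the channel")
        fld = solve_steady_transport(geom, params, flows, tube_lateral_um=y_tube,
                                     grid=grid)
        out.append({"offset_um": off,
                    "dc_mM": tip_concentration_difference(fld, y_tube)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# fluorescence calibration and diffusion-coefficient estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluorCalibration:
    """Log-linear Fluo-3 calibration: signal = slope·log10(c_mM) + intercept."""

    slope: float
    intercept: float
    valid_range_mM: tuple[float, float] = FLUO3_LINEAR_RANGE_MM
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise TransportError("calibration slope must be non-zero")

    def forward(self, conc_mM: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.log10(conc_mM) + self.intercept

    def inverse(self, signal: np.ndarray | float) -> np.ndarray | float:
        return 10.0 ** ((signal - self.intercept) / self.slope)


def fit_fluorescence_calibration(
    known_conc_mM: np.ndarray | list[float],
    signals: np.ndarray | list[float],
) -> FluorCalibration:
    """Least-squares line of signal on log10(known Ca2+ concentration).

    Concentrations outside the Fluo-3 linear range (2e-3 to 1 mM) are
    flagged with a warning (they likely saturate) but still fitted.
    """
    c = np.asarray(known_conc_mM, dtype=float)
    s = np.asarray(signals, dtype=float)
    if c.shape != s.shape or c.size < 2 or np.unique(c).size < 2:
        raise TransportError("need >= 2 distinct concentrations with signals")
    lo, hi = FLUO3_LINEAR_RANGE_MM
    n_out = int(np.sum((c < lo) | (c > hi)))
    if n_out:
        warnings.warn(
            f"{n_out} calibration concentration(s) outside the Fluo-3 linear "
            f"range [{lo}, {hi}] mM", stacklevel=2)
    logc = np.log10(c)
    slope, intercept = np.polyfit(logc, s, 1)
    pred = slope * logc + intercept
    ss_res = float(np.sum((s - pred) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FluorCalibration(float(slope), float(intercept), (lo, hi), r2)


def signal_to_concentration(
    apparent_signal: np.ndarray,
    baseline_signal: np.ndarray,
    cal: FluorCalibration,
) -> tuple[np.ma.MaskedArray, int]:
    """Invert corrected fluorescence signals to Ca2+ concentrations, mM.

    The baseline (illumination background) is subtracted first; samples
    with non-positive corrected signal or outside the calibrated signal
    range are masked, never clipped silently.  Returns the masked
    profile and the number of masked samples.
    """
    apparent = np.asarray(apparent_signal, dtype=float)
    baseline = np.asarray(baseline_signal, dtype=float)
    if apparent.shape != baseline.shape:
        raise TransportError("apparent and baseline profiles differ in length")
    corrected = apparent - baseline
    s_lo, s_hi = sorted((cal.forward(cal.valid_range_mM[0]),
                         cal.forward(cal.valid_range_mM[1])))
    bad = (corrected <= 0) | (corrected < s_lo) | (corrected > s_hi)
    n_masked = int(bad.sum())
    if np.any(corrected <= 0):
        warnings.warn(
            f"{int(np.sum(corrected <= 0))} sample(s) with non-positive "
            "corrected signal were masked", stacklevel=2)
    conc = np.where(bad, np.nan, cal.inverse(np.where(bad, 1.0, corrected)))
    return np.ma.masked_invalid(conc), n_masked


def estimate_diffusion_coefficient(
    measured_profile: pd.DataFrame,
    geom: ChannelGeometry,
    params: TransportParams,
    flows: StreamFlows,
    candidates: list[float],
    station_um: float | None = None,
    grid: GridSpec = GridSpec(),
) -> tuple[float, pd.DataFrame]:
    """Pick the diffusion coefficient best matching a measured profile.

    For every candidate D the steady field is re-solved (no obstacle)
    and its cross-channel profile at the measurement station compared to
    the measured one (columns position_um, concentration_mM) by
    sum-of-squares.  Returns (best D, score table); ties break toward
    the smaller D.
    """
    if not candidates:
        raise TransportError("need at least one candidate diffusion coefficient")
    if station_um is None:
        station_um = geom.tip_streamwise_position
    y_meas = measured_profile["position_um"].to_numpy(dtype=float)
    c_meas = measured_profile["concentration_mM"].to_numpy(dtype=float)
    scores = []
    for d_cand in sorted(candidates):
        p = TransportParams(
            diffusion_coefficient=d_cand, tfr=params.tfr,
            inlet_concentrations=params.inlet_concentrations,
            density=params.density, viscosity=params.viscosity)
        fld = solve_steady_transport(geom, p, flows, grid=grid)
        prof = fld.profile_at(station_um)
        c_sim = np.interp(y_meas, prof["position_um"], prof["concentration_mM"])
        scores.append({"D_m2_s": d_cand,
                       "sse": float(np.sum((c_sim - c_meas) ** 2))})
    table = pd.DataFrame(scores)
    # idxmin takes the first minimum; the table is sorted ascending in D,
    # so ties already break toward the smaller candidate
    best = float(table.loc[table["sse"].idxmin(), "D_m2_s"])
    return best, table
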