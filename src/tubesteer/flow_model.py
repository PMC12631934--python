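"""Hydrodynamic flow-focusing arithmetic for the 4-inlet co-flow device.

The device merges four inlets into three co-flowing laminar streams in the
main channel: stream 1 (inlet 1), the middle stream (inlets 2+3) and
stream 3 (inlet 4).  Two interfaces separate them; their dimensionless
lateral positions ``m3 <= m2`` (0 = wall on the stream-3 side, 1 = wall on
the stream-1 side) are set by the relative flow rates at constant total
flow rate (TFR).  This module holds the flow-rate ratios, the ideal and
calibrated linear flow->position maps, and the flow-rate constraints the
controller must respect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InletFlows",
    "StreamFlows",
    "InterfacePositions",
    "LinearPlantModel",
    "ConstraintReport",
    "FlowModelError",
    "compute_ratios",
    "ideal_interface_positions",
    "flows_from_targets",
    "calibrate_linear_model",
    "check_constraints",
    "read_calibration_sweep",
    "write_calibration_sweep",
]

#: Absolute tolerance used for the exact-sum constraint f1+f2+f3 = TFR.
SUM_TOL = 1e-9


class FlowModelError(ValueError):
    """Invalid flows, targets or calibration data."""


@dataclass(frozen=True)
class InletFlows:
    """Flow rates of the four device inlets, µL/min."""

    v1: float
    v2: float
    v3: float
    v4: float

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "v3", "v4"):
            if getattr(self, name) < 0:
                raise FlowModelError(f"inlet flow {name} must be >= 0")

    @property
    def tfr(self) -> float:
        return self.v1 + self.v2 + self.v3 + self.v4

    def to_streams(self) -> "StreamFlows":
        """Map inlets to the three co-flowing streams (f1=v1, f2=v2+v3, f3=v4)."""
        return StreamFlows(self.v1, self.v2 + self.v3, self.v4)


@dataclass(frozen=True)
class StreamFlows:
    """Flow rates of the three co-flowing streams, µL/min.

    ``f1`` flows along the m=1 wall, ``f3`` along the m=0 wall, ``f2`` in
    between.  TFR is their sum; the constraints 0 <= fi <= TFR and
    f1+f2+f3 = TFR are structural.
    """

    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        for name in ("f1", "f2", "f3"):
            if getattr(self, name) < -SUM_TOL:
                raise FlowModelError(f"stream flow {name} must be >= 0")

    @property
    def tfr(self) -> float:
        return self.f1 + self.f2 + self.f3

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3], dtype=float)


@dataclass(frozen=True)
class InterfacePositions:
    """Dimensionless lateral interface positions, 0 <= m3 <= m2 <= 1.

    m3 separates stream 3 from the middle stream, m2 the middle stream
    from stream 1.  The origin is the wall adjacent to stream 3.
    """

    m3: float
    m2: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.m3 <= self.m2 <= 1 + 1e-12):
            raise FlowModelError(
                f"interface positions must satisfy 0 <= m3 <= m2 <= 1, "
                f"got m3={self.m3}, m2={self.m2}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.m3, self.m2], dtype=float)


@dataclass(frozen=True)
class LinearPlantModel:
    """Linear interface-position response: m3 = b3*f3, m2 = m3 + b2*f2.

    b2, b3 are interface displacement per unit flow, (µL/min)^-1; in the
    ideal (uncalibrated) device both equal 1/TFR.  ``process_noise_sd``
    is the per-tick random model error of the discrete plant.
    """

    b2: float
    b3: float
    process_noise_sd: float = 0.0
    fit_flow_range: tuple[float, float] | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.b2 <= 0 or self.b3 <= 0:
            raise FlowModelError("b2 and b3 must be > 0")

    @classmethod
    def ideal(cls, tfr: float, process_noise_sd: float = 0.0) -> "LinearPlantModel":
        if tfr <= 0:
            raise FlowModelError("TFR must be > 0")
        return cls(b2=1.0 / tfr, b3=1.0 / tfr, process_noise_sd=process_noise_sd)

    def positions(self, f: StreamFlows) -> InterfacePositions:
        m3 = self.b3 * f.f3
        m2 = m3 + self.b2 * f.f2
        return InterfacePositions(m3, m2)

    def in_fitted_range(self, f: StreamFlows) -> bool:
        """Flag (not error) extrapolation beyond the calibrated flow range."""
        if self.fit_flow_range is None:
            return True
        lo, hi = self.fit_flow_range
        return all(lo - 1e-12 <= x <= hi + 1e-12 for x in (f.f1, f.f2, f.f3))


def compute_ratios(v: InletFlows) -> tuple[float, float]:
    """Flow-rate ratio and asymmetric flow-rate ratio of a 4-inlet setting.

    FRR = (v2+v3)/TFR sets the middle-stream width; AFRR =
    (v4 + 0.5(v2+v3))/TFR sets the middle stream's centreline position.
    """
    tfr = v.tfr
    if tfr <= 0:
        raise FlowModelError("total flow rate must be > 0")
    frr = (v.v2 + v.v3) / tfr
    afrr = (v.v4 + 0.5 * (v.v2 + v.v3)) / tfr
    return frr, afrr


def ideal_interface_positions(f: StreamFlows) -> InterfacePositions:
    """Interface positions as cumulative flow fractions (ideal device).

    m3 = f3/TFR and m2 = (f3+f2)/TFR, i.e. b2 = b3 = 1/TFR.  The
    midpoint (m2+m3)/2 equals the AFRR and the width m2-m3 equals the
    FRR of the same flows.
    """
    tfr = f.tfr
    if tfr <= 0:
        raise FlowModelError("total flow rate must be > 0")
    return InterfacePositions(f.f3 / tfr, (f.f3 + f.f2) / tfr)


def flows_from_targets(r: InterfacePositions, tfr: float) -> StreamFlows:
    """Invert the ideal map: stream flows that place the interfaces at ``r``."""
    if tfr <= 0:
        raise FlowModelError("TFR must be > 0")
    if r.m3 > r.m2:
        raise FlowModelError("invalid target: m3 > m2")
    f3 = r.m3 * tfr
    f2 = (r.m2 - r.m3) * tfr
    f1 = tfr - f2 - f3
    return StreamFlows(f1, f2, f3)


@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of checking the flow-rate constraints (never raises)."""

    ok: bool
    bound_violations: tuple[str, ...] = ()
    sum_violation: float = 0.0

    def __bool__(self) -> bool:
        return self.ok


def check_constraints(
    f_next: StreamFlows, f_prev: StreamFlows | None = None, tfr: float | None = None
) -> ConstraintReport:
    """Check 0 <= fi <= TFR and f1+f2+f3 = TFR (exactly, within 1e-9).

    The reference TFR is taken from ``tfr`` if given, else from
    ``f_prev`` (constant-TFR repositioning), else from ``f_next`` itself.
    """
    if tfr is None:
        tfr = f_prev.tfr if f_prev is not None else f_next.tfr
    bad = [
        name
        for name, x in zip(("f1", "f2", "f3"), f_next.as_array())
        if x < -SUM_TOL or x > tfr + SUM_TOL
    ]
    dsum = f_next.tfr - tfr
    ok = not bad and abs(dsum) <= SUM_TOL
    return ConstraintReport(ok, tuple(bad), dsum if abs(dsum) > SUM_TOL else 0.0)


def calibrate_linear_model(
    sweep: list[tuple[StreamFlows, InterfacePositions]],
    process_noise_sd: float = 0.0,
) -> LinearPlantModel:
    """Fit b3, b2 by least squares from a flow sweep with observed positions.

    b3 is the through-origin slope of m3 on f3 and b2 the through-origin
    slope of (m2 - m3) on f2, matching the linear device response.
    Residual diagnostics (pooled residual sd) and the fitted flow range
    are stored on the returned model; settings outside that range are
    flagged by :meth:`LinearPlantModel.in_fitted_range`, not rejected.
    """
    if len(sweep) < 2:
        raise FlowModelError("calibration needs at least 2 sweep points")
    f3 = np.array([f.f3 for f, _ in sweep])
    f2 = np.array([f.f2 for f, _ in sweep])
    m3 = np.array([m.m3 for _, m in sweep])
    dm = np.array([m.m2 - m.m3 for _, m in sweep])
    if np.allclose(f3, f3[0]) or np.dot(f3, f3) == 0:
        raise FlowModelError("rank-deficient sweep: all f3 identical")
    if np.dot(f2, f2) == 0:
        raise FlowModelError("rank-deficient sweep: all f2 zero")
    b3 = float(np.dot(f3, m3) / np.dot(f3, f3))
    b2 = float(np.dot(f2, dm) / np.dot(f2, f2))
    resid = np.concatenate([m3 - b3 * f3, dm - b2 * f2])
    residual_sd = float(np.sqrt(np.mean(resid**2)))
    flows = np.concatenate([f3, f2, [f.f1 for f, _ in sweep]])
    return LinearPlantModel(
        b2=b2,
        b3=b3,
        process_noise_sd=process_noise_sd,
        fit_flow_range=(float(flows.min()), float(flows.max())),
        residual_sd=residual_sd,
    )


# --- calibration sweep I/O (CSV: f1,f2,f3,m3_obs,m2_obs) ----------------

_SWEEP_COLUMNS = ["f1", "f2", "f3", "m3_obs", "m2_obs"]


def read_calibration_sweep(path_or_buf) -> list[tuple[StreamFlows, InterfacePositions]]:
    df = pd.read_csv(path_or_buf)
    missing = [c for c in _SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise FlowModelError(f"calibration CSV missing columns: {missing}")
    return [
        (StreamFlows(r.f1, r.f2, r.f3), InterfacePositions(r.m3_obs, r.m2_obs))
        for r in df.itertuples()
    ]


def write_calibration_sweep(
    sweep: list[tuple[StreamFlows, InterfacePositions]], path_or_buf
) -> None:
    rows = [
        {"f1": f.f1, "f2": f.f2, "f3": f.f3, "m3_obs": m.m3, "m2_obs": m.m2}
        for f, m in sweep
    ]
    pd.DataFrame(rows, columns=_SWEEP_COLUMNS).to_csv(path_or_buf, index=False)
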