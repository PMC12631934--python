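"""Trajectory post-processing: turning events, angles and summaries.

Takes tip trajectories (from the trackers or the digital twin),
smooths the growth direction over a trailing arc, detects sustained
turning events, and aggregates experiments into the turning proportion
and turning-angle statistics (mean, median, quartiles, 1.5-IQR
whiskers, outliers) used to compare experimental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TurningEvent",
    "ExperimentSummary",
    "AnalysisError",
    "growth_direction",
    "detect_turning",
    "summarize",
]


class AnalysisError(ValueError):
    """Invalid trajectory or summary input."""


@dataclass
class Trajectory:
    """Time-ordered tip track with physical scale.

    positions are (n, 2) as (row, col) px or (x, y) — any planar frame
    works, direction conventions follow the (row, col) image frame used
    by the trackers (0° = +col, counter-clockwise positive).
    """

    t_s: np.ndarray
    positions_px: np.ndarray
    pixel_size_um: float = 2.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.t_s), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.t_s) <= 0):
            raise AnalysisError("timestamps must be strictly increasing")
        if len(self.positions_px) != len(self.t_s):
            raise AnalysisError("positions and timestamps differ in length")


def growth_direction(traj: Trajectory, arc_window_um: float = 20.0
                     ) -> np.ndarray:
    """Smoothed, unwrapped growth direction series, degrees.

    The direction at each frame is the orientation of the secant over
    the trailing arc of the stated length (image convention, 0° = +col,
    counter-clockwise positive with row increasing downward); the first
    frames reuse the first full-window estimate.  Angles are unwrapped,
    so they may leave [0, 360).
    """
    pts = traj.positions_px[traj.valid] * traj.pixel_size_um
    if len(pts) < 2:
        raise AnalysisError("need >= 2 valid points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    if arc[-1] < arc_window_um:
        raise AnalysisError("trajectory shorter than the arc window")
    dirs = np.full(len(pts), np.nan)
    for i in range(len(pts)):
        target = arc[i] - arc_window_um
        if target < 0:
            continue
        j = int(np.searchsorted(arc, target))
        j = min(j, i - 1)
        d = pts[i] - pts[j]
        dirs[i] = np.degrees(np.arctan2(-d[0], d[1]))
    first = np.flatnonzero(~np.isnan(dirs))[0]
    dirs[:first] = dirs[first]
    dirs = np.degrees(np.unwrap(np.radians(dirs)))
    out = np.full(len(traj.t_s), np.nan)
    out[traj.valid] = dirs
    # carry the last smoothed value through invalid frames
    for i in range(1, len(out)):
        if np.isnan(out[i]):
            out[i] = out[i - 1]
    first = np.flatnonzero(~np.isnan(out))[0]
    out[:first] = out[first]
    return out


@dataclass(frozen=True)
class TurningEvent:
    """A sustained change of growth direction."""

    t_start_s: float
    t_end_s: float
    pre_direction_deg: float
    post_direction_deg: float
    side: int = 0  # +1 toward the stream-1 wall, -1 toward stream-3

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise AnalysisError("event must end after it starts")

    @property
    def angle_deg(self) -> float:
        """Unsigned turning angle on [0, 180]."""
        d = abs(self.post_direction_deg - self.pre_direction_deg) % 360.0
        return d if d <= 180.0 else 360.0 - d


def detect_turning(
    traj: Trajectory,
    min_angle_deg: float = 10.0,
    persistence_s: float = 30.0,
    arc_window_um: float = 20.0,
    directions_deg: np.ndarray | None = None,
) -> list[TurningEvent]:
    """Detect non-overlapping turning events in a trajectory.

    An event opens when the cumulative direction change since the
    running reference heading exceeds ``min_angle_deg`` and the new
    heading persists (change of less than ``min_angle_deg`` relative to
    the post-turn heading) for at least ``persistence_s``.  Multiple
    events are allowed; the post-heading of one event seeds the
    reference of the next.
    """
    dirs = (directions_deg if directions_deg is not None
            else growth_direction(traj, arc_window_um))
    t = traj.t_s
    events: list[TurningEvent] = []
    ref = dirs[0]
    i = 1
    n = len(dirs)
    while i < n:
        if abs(dirs[i] - ref) >= min_angle_deg:
            t_start = t[i - 1]
            # let the turn develop: advance while the heading keeps moving
            j = i
            while j + 1 < n and abs(dirs[j + 1] - dirs[j]) > 1.0:
                j += 1
            post = dirs[j]
            # persistence check on the new heading
            k = j
            persistent = True
            while k < n and t[k] - t[j] < persistence_s:
                if abs(dirs[k] - post) >= min_angle_deg:
                    persistent = False
                    break
                k += 1
            if k >= n and t[n - 1] - t[j] < persistence_s:
                persistent = False  # ran out of track before persisting
            if persistent:
                events.append(TurningEvent(
                    t_start_s=float(t_start), t_end_s=float(t[j]),
                    pre_direction_deg=float(ref),
                    post_direction_deg=float(post),
                    side=int(np.sign(post - ref))))
                ref = post
                i = k
            else:
                ref = post
                i = j + 1
        else:
            i += 1
    return events


@dataclass(frozen=True)
class ExperimentSummary:
    """Experiment-level turning statistics (first-turn angles)."""

    n_experiments: int
    n_turned: int
    angle_mean: float
    angle_median: float
    angle_q1: float
    angle_q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    angle_sd: float

    @property
    def turning_proportion(self) -> float:
        return self.n_turned / self.n_experiments

    def to_dict(self) -> dict:
        return {
            "n_experiments": self.n_experiments,
            "n_turned": self.n_turned,
            "turning_proportion": self.turning_proportion,
            "angle_mean_deg": self.angle_mean,
            "angle_median_deg": self.angle_median,
            "angle_q1_deg": self.angle_q1,
            "angle_q3_deg": self.angle_q3,
            "whisker_low_deg": self.whisker_low,
            "whisker_high_deg": self.whisker_high,
            "angle_sd_deg": self.angle_sd,
            "outliers_deg": list(self.outliers),
        }


def summarize(
    experiments: list[tuple[Trajectory, list[TurningEvent]]],
) -> ExperimentSummary:
    """Aggregate experiments into proportion and first-turn angle stats.

    The proportion counts experiments with at least one event; angle
    statistics are over the first-turn angle of each turned experiment.
    Quartiles use linear interpolation; whiskers sit at 1.5 IQR beyond
    the quartiles (clipped to the data), points beyond are outliers.
    """
    if not experiments:
        raise AnalysisError("need at least one experiment")
    angles = np.array([ev[0].angle_deg for _, ev in experiments if ev])
    n_turned = len(angles)
    if n_turned == 0:
        nan = float("nan")
        return ExperimentSummary(len(experiments), 0, nan, nan, nan, nan,
                                 nan, nan, (), nan)
    q1, med, q3 = np.percentile(angles, [25, 50, 75])
    iqr = q3 - q1
    in_lo = angles[angles >= q1 - 1.5 * iqr]
    in_hi = angles[angles <= q3 + 1.5 * iqr]
    wlo = float(in_lo.min()) if len(in_lo) else float(angles.min())
    whi = float(in_hi.max()) if len(in_hi) else float(angles.max())
    outliers = tuple(float(a) for a in angles
                     if a < q1 - 1.5 * iqr or a > q3 + 1.5 * iqr)
    sd = float(np.std(angles, ddof=1)) if n_turned > 1 else 0.0
    return ExperimentSummary(
        n_experiments=len(experiments), n_turned=n_turned,
        angle_mean=float(np.mean(angles)), angle_median=float(med),
        angle_q1=float(q1), angle_q3=float(q3),
        whisker_low=wlo, whisker_high=whi, outliers=outliers, angle_sd=sd)


def events_to_frame(events_by_experiment: dict[str, list[TurningEvent]]
                    ) -> pd.DataFrame:
    """Tidy events table (experiment_id, t_start, t_end, pre, post, angle)."""
    rows = []
    for exp_id, events in events_by_experiment.items():
        for ev in events:
            rows.append({
                "experiment_id": exp_id,
                "t_start_s": ev.t_start_s, "t_end_s": ev.t_end_s,
                "pre_deg": ev.pre_direction_deg,
                "post_deg": ev.post_direction_deg,
                "angle_deg": ev.angle_deg,
            })
    return pd.DataFrame(rows, columns=["experiment_id", "t_start_s", "t_end_s",
                                       "pre_deg", "post_deg", "angle_deg"])
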