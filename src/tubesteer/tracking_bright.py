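"""Brightfield pollen-tube tracking by fusion of three cues.

Brightfield frames of the device are poor in texture, so no single
method tracks the growing tube reliably.  Each frame is dispatched on
the dense optical-flow magnitude between consecutive frames:

* small magnitude (little growth) -> contour path: Canny edges, closed
  near-convex contour selection, ellipse fit; the tip is the major-axis
  endpoint away from the frame entry side.
* large magnitude -> motion path: per-pixel k-nearest-sample background
  subtraction (a self-contained KNN background model), DBSCAN on the
  foreground pixels, tip = extreme cluster point along the last known
  growth direction.

Both paths feed the same outlier-rejection rule as the fluorescence
tracker.  The dispatch is a pure function of the frames and the
threshold, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import gaussian
from skimage.measure import label, regionprops
from sklearn.cluster import DBSCAN

from .tracking_fluor import Frame, ROI, TipDetection, TrackingError, \
    validate_detection

__all__ = [
    "KNNBackgroundModel",
    "MotionState",
    "flow_magnitude",
    "contour_tip",
    "motion_tip",
    "track_frame",
    "BrightfieldTracker",
]


class KNNBackgroundModel:
    """Per-pixel k-nearest-sample background model.

    Keeps up to ``history`` intensity samples per pixel; a pixel is
    foreground when fewer than ``k`` stored samples lie within
    ``dist_threshold`` of its current intensity.  Samples are replaced
    cyclically, so the model adapts to slow illumination drift.
    """

    def __init__(self, k: int = 3, history: int = 50,
                 dist_threshold: float = 12.0):
        self.k = k
        self.history = history
        self.dist_threshold = dist_threshold
        self._samples: np.ndarray | None = None  # (history, H, W)
        self._n_seen = 0

    @property
    def warmed(self) -> bool:
        return self._n_seen >= 1

    def apply(self, image: np.ndarray, learn: bool = True) -> np.ndarray:
        """Foreground mask for ``image``; optionally absorb it as a sample.

        The match distance adapts to the sensor noise (robust MAD of
        the difference against the newest stored sample), so Poisson-
        dominated frames do not light up everywhere.
        """
        img = np.asarray(image, dtype=float)
        if self._samples is None:
            self._samples = np.empty((self.history, *img.shape))
        n = min(self._n_seen, self.history)
        if n == 0:
            fg = np.zeros(img.shape, dtype=bool)
        else:
            ref = self._samples[(self._n_seen - 1) % self.history]
            d = img - ref
            noise_sd = 1.4826 * np.median(np.abs(d - np.median(d)))
            thr = max(self.dist_threshold, 4.5 * noise_sd)
            close = np.abs(self._samples[:n] - img[None]) <= thr
            fg = close.sum(axis=0) < min(self.k, n)
        if learn:
            self._samples[self._n_seen % self.history] = img
            self._n_seen += 1
        return fg


@dataclass
class MotionState:
    """Rolling state of the fusion tracker."""

    previous: Frame | None = None
    background: KNNBackgroundModel = field(default_factory=KNNBackgroundModel)
    flow_threshold: float = 1.0  # px/frame at the 95th percentile
    last: TipDetection = field(default_factory=TipDetection)
    history: list[TipDetection] = field(default_factory=list)
    roi_half_size: int = 40
    max_step_px: float = 20.0
    max_turn_deg: float = 45.0
    path_taken: str = "contour"

    def __post_init__(self) -> None:
        if self.flow_threshold <= 0:
            raise TrackingError("flow magnitude threshold must be > 0")


SMOOTH_SIGMA = 1.5  # pre-smoothing for the dense flow statistic


def flow_magnitude(prev: Frame, cur: Frame,
                   window: tuple[slice, slice] | None = None) -> float:
    """95th-percentile dense normal-flow magnitude, px/frame.

    Dense optical flow is only well-posed along intensity gradients, so
    the statistic uses the normal-flow magnitude |ΔI|/|∇I| at pixels
    whose gradient clearly exceeds the sensor noise floor (estimated
    robustly from the frame difference); the expected noise
    contribution is subtracted from |ΔI| first, so a static noisy pair
    scores ~0.  ``window`` restricts the statistic to a region — the
    tracker passes the ROI around the last tip, where growth shows.
    """
    a, b = prev.image, cur.image
    if a.shape != b.shape:
        raise TrackingError("frame shapes differ")
    if window is not None:
        a, b = a[window], b[window]
    diff_raw = b - a
    noise_sd = 1.4826 * np.median(np.abs(diff_raw - np.median(diff_raw))) \
        / np.sqrt(2)
    a_s = gaussian(a, sigma=SMOOTH_SIGMA, preserve_range=True)
    b_s = gaussian(b, sigma=SMOOTH_SIGMA, preserve_range=True)
    # noise sd surviving the Gaussian smoothing
    sd_s = noise_sd / (2.0 * np.sqrt(np.pi) * SMOOTH_SIGMA)
    grad = np.hypot(*np.gradient(a_s))
    well_posed = grad > max(5.0 * sd_s, 1e-9)
    if not np.any(well_posed):
        return 0.0
    diff = np.maximum(np.abs(b_s - a_s) - 3.0 * np.sqrt(2.0) * sd_s, 0.0)
    vn = diff[well_posed] / grad[well_posed]
    return float(np.percentile(vn, 95))


def contour_tip(frame: Frame, sigma: float = 2.0,
                convexity_threshold: float = 0.85,
                min_area_px: int = 80,
                entry_side: str = "left") -> TipDetection:
    """Tip from Canny edges, convex-contour recognition and ellipse fit.

    The tube's dark halo traces a closed Canny contour; after closing
    small gaps and filling, regions whose area is at least
    ``convexity_threshold`` of their convex hull are near-convex tube
    candidates (the capsule is convex, debris and wall shadows are
    not).  The moment (inertia-equivalent) ellipse of the largest
    candidate gives the centreline axis; the tip is the mean of the
    extreme region pixels along the axis away from the frame entry
    side.  A near-circular ellipse (degenerate axis) yields a
    low-confidence detection.
    """
    # quantile thresholds keep only the strongest edges (the tube halo);
    # absolute defaults drown low-contrast brightfield frames in noise
    edges = canny(frame.image, sigma=sigma, use_quantiles=True,
                  low_threshold=0.90, high_threshold=0.99)
    # cap the entry-side column so the tube, which enters the view from
    # that side, closes into a fillable contour
    edges[:, 0 if entry_side == "left" else -1] = True
    closed = ndimage.binary_closing(edges, structure=np.ones((5, 5)))
    filled = ndimage.binary_fill_holes(closed)
    labels = label(filled)
    background = float(np.median(frame.image))
    best = None
    for region in regionprops(labels, intensity_image=frame.image):
        if region.area < min_area_px:
            continue
        if region.area / region.area_convex < convexity_threshold:
            continue
        # the tube reads darker than the background (its halo); bright
        # interface ridges and illumination bands are not candidates
        if region.intensity_mean > background - 2.0:
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None:
        return TipDetection()
    ang = best.orientation + np.pi / 2  # orientation is w.r.t. the row axis
    axis = np.array([-np.sin(ang), np.cos(ang)])  # (row, col) unit vector
    center = np.asarray(best.centroid)
    entry_col = 0.0 if entry_side == "left" else frame.image.shape[1] - 1.0
    if (center[1] - entry_col) * axis[1] < 0:
        axis = -axis
    pixels = np.asarray(best.coords, dtype=float)
    proj = (pixels - center) @ axis
    tip = pixels[np.argsort(proj)[-5:]].mean(axis=0)
    direction = float(np.degrees(np.arctan2(-axis[0], axis[1])))
    aspect = best.axis_major_length / max(best.axis_minor_length, 1e-9)
    confidence = float(np.clip((aspect - 1.0) / 1.0, 0.05, 1.0))
    return TipDetection(position=(float(tip[0]), float(tip[1])),
                        direction_deg=direction, valid=True,
                        confidence=confidence)


def motion_tip(state: MotionState, cur: Frame, dbscan_eps: float = 3.0,
               dbscan_min_samples: int = 8, learn: bool = True) -> TipDetection:
    """Tip from background-subtraction foreground plus DBSCAN.

    Requires a warmed background model; the cluster nearest the last
    tip is selected and its extreme point along the last growth
    direction is the tip.
    """
    if not state.background.warmed:
        raise TrackingError("background model not warmed (needs >= 1 frame)")
    fg = state.background.apply(cur.image, learn=learn)
    pts = np.column_stack(np.nonzero(fg)).astype(float)
    if len(pts) < dbscan_min_samples:
        return TipDetection()
    labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit(pts).labels_
    if labels.max() < 0:
        return TipDetection()
    clusters = [pts[labels == k] for k in range(labels.max() + 1)]
    if state.last.valid:
        prev = np.asarray(state.last.position)
        cluster = min(clusters,
                      key=lambda c: np.min(np.linalg.norm(c - prev, axis=1)))
        ang = np.deg2rad(state.last.direction_deg)
        axis = np.array([-np.sin(ang), np.cos(ang)])
    else:
        cluster = max(clusters, key=len)
        axis = np.array([0.0, 1.0])
    proj = cluster @ axis
    order = np.argsort(proj)[-3:]
    tip = cluster[order].mean(axis=0)
    direction = float(np.degrees(np.arctan2(-axis[0], axis[1])))
    return TipDetection(position=(float(tip[0]), float(tip[1])),
                        direction_deg=direction, valid=True,
                        confidence=min(1.0, len(cluster) / 100.0))


def track_frame(state: MotionState, cur: Frame) -> tuple[TipDetection, MotionState]:
    """One fusion-tracker step: dispatch on flow magnitude, then validate.

    Contour path when the 95th-percentile optical-flow magnitude is
    below the threshold, motion path otherwise; the accepted/rejected
    decision uses the same history rule as the fluorescence tracker.
    When both paths fail the detection is invalid and the last state is
    retained.
    """
    if state.previous is None:
        det = contour_tip(cur)
        path = "contour"
    else:
        window = None
        if state.last.valid:
            window = ROI(state.last.position,
                         state.roi_half_size).slices(cur.image.shape)
        mag = flow_magnitude(state.previous, cur, window=window)
        if mag < state.flow_threshold or not state.background.warmed:
            det = contour_tip(cur)
            path = "contour"
        else:
            det = motion_tip(state, cur, learn=False)
            path = "motion"
    state.background.apply(cur.image, learn=True)
    roi = ROI(det.position if det.valid else (state.last.position
              if state.last.valid else (0.0, 0.0)), state.roi_half_size)
    ok, _ = validate_detection(det, state.history, roi, state.max_step_px,
                               state.max_turn_deg,
                               frame_shape=cur.image.shape)
    det = det if ok else replace(det, valid=False)
    new_state = replace(state, previous=cur, path_taken=path,
                        last=det if det.valid else state.last,
                        history=state.history + [det])
    return det, new_state


@dataclass
class BrightfieldTracker:
    """Convenience wrapper running :func:`track_frame` over a sequence."""

    state: MotionState = field(default_factory=MotionState)
    paths: list[str] = field(default_factory=list)

    def track(self, frame: Frame) -> TipDetection:
        det, self.state = track_frame(self.state, frame)
        self.paths.append(getattr(self.state, "path_taken", "contour"))
        return det
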