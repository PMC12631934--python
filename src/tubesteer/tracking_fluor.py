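"""Fluorescence tracking: pollen-tube tip and co-flow interface curves.

Two pipelines run on each fluorescence frame of the main channel:

* Tip localization — Gaussian + median preprocessing, adaptive
  (local-mean) thresholding inside a region of interest (ROI), DBSCAN
  to isolate the tube-tip pixel cluster, a ring-intersection centreline
  construction to get the growth direction, outlier rejection against
  the track history, and ROI re-centering on success.
* Interface detection — histogram-shape-adaptive contrast stretch, an
  image pyramid with adaptive thresholding per level combined by
  majority vote, DBSCAN filtering of the boundary pixels, and reduction
  of each kept cluster to a seeded random sample of curve points.

Image convention: row = y (lateral), col = x (streamwise), origin
top-left.  Directions are degrees, 0° = +x, counter-clockwise positive
(so "up" in the image, decreasing row, is +90°).  The controller's
normalized lateral coordinate m runs from 1 at the top wall (stream 1)
to 0 at the bottom wall (stream 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, median, threshold_local
from skimage.measure import block_reduce
from skimage.morphology import footprint_rectangle
from skimage.transform import resize
from sklearn.cluster import DBSCAN

__all__ = [
    "Frame",
    "ROI",
    "TipDetection",
    "InterfaceCurve",
    "TrackingError",
    "preprocess",
    "segment_tip_region",
    "locate_tip",
    "validate_detection",
    "detect_interfaces",
    "interface_position_at",
    "FluorescenceTipTracker",
]


class TrackingError(ValueError):
    """Invalid tracking parameters or inputs."""


@dataclass(frozen=True)
class Frame:
    """Single grayscale frame with physical scale and timestamp."""

    image: np.ndarray  # 2-D float or integer intensities, >= 0
    pixel_size_um: float = 2.0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise TrackingError("frame must be a 2-D intensity grid")
        if self.pixel_size_um <= 0:
            raise TrackingError("pixel size must be > 0")
        if np.min(img) < 0:
            raise TrackingError("negative intensities")
        object.__setattr__(self, "image", img.astype(float))


@dataclass(frozen=True)
class ROI:
    """Square region of interest: centre (row, col) and half-size, px."""

    center: tuple[float, float]
    half_size: int

    def clamped(self, shape: tuple[int, int]) -> "ROI":
        """ROI shifted to lie fully inside a frame of the given shape."""
        r = float(np.clip(self.center[0], self.half_size,
                          shape[0] - 1 - self.half_size))
        c = float(np.clip(self.center[1], self.half_size,
                          shape[1] - 1 - self.half_size))
        return ROI((r, c), self.half_size)

    def slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        roi = self.clamped(shape)
        r0 = int(round(roi.center[0] - roi.half_size))
        c0 = int(round(roi.center[1] - roi.half_size))
        side = 2 * roi.half_size + 1
        return slice(r0, r0 + side), slice(c0, c0 + side)


@dataclass(frozen=True)
class TipDetection:
    """Sub-pixel tip position (row, col), growth direction and validity."""

    position: tuple[float, float] = (np.nan, np.nan)
    direction_deg: float = 0.0
    valid: bool = False
    confidence: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction_deg", self.direction_deg % 360.0)


@dataclass(frozen=True)
class InterfaceCurve:
    """Sampled interface curve: points (row, col) sorted by streamwise col."""

    points: np.ndarray  # (n, 2) float, columns strictly sorted

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3:
            raise TrackingError("interface curve needs >= 3 points")
        order = np.argsort(pts[:, 1], kind="stable")
        object.__setattr__(self, "points", pts[order])

    @property
    def mean_lateral(self) -> float:
        return float(np.mean(self.points[:, 0]))


# ---------------------------------------------------------------------------
# tip pipeline
# ---------------------------------------------------------------------------


def preprocess(frame: Frame, gaussian_sigma: float = 1.0,
               median_width: int = 3) -> Frame:
    """Gaussian blur then median filter; intensity range is preserved."""
    if median_width % 2 == 0:
        raise TrackingError("median width must be odd")
    img = gaussian(frame.image, sigma=gaussian_sigma, preserve_range=True)
    img = median(img, footprint_rectangle((median_width, median_width)))
    return replace(frame, image=img)


def segment_tip_region(
    frame: Frame,
    roi: ROI,
    block_size: int = 31,
    offset: float = 2.0,
    dbscan_eps: float = 3.0,
    dbscan_min_samples: int = 8,
    previous_tip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Foreground pixel cluster of the tube tip inside the ROI.

    Local-mean adaptive thresholding inside the ROI, then DBSCAN on the
    foreground pixel coordinates; returns the cluster nearest the
    previous tip (largest cluster when no history), as (n, 2) absolute
    (row, col) coordinates — empty on failure, never an exception.
    """
    rs, cs = roi.slices(frame.image.shape)
    patch = frame.image[rs, cs]
    if patch.size == 0 or np.ptp(patch) == 0:
        return np.empty((0, 2))
    thr = threshold_local(patch, block_size=block_size, method="mean",
                          offset=offset)
    fg = np.column_stack(np.nonzero(patch > thr)).astype(float)
    if len(fg) < dbscan_min_samples:
        return np.empty((0, 2))
    labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit(fg).labels_
    keep = labels >= 0
    if not np.any(keep):
        return np.empty((0, 2))
    clusters = [fg[labels == k] for k in range(labels.max() + 1)]
    if previous_tip is not None:
        prev = np.array([previous_tip[0] - rs.start, previous_tip[1] - cs.start])
        score = [np.min(np.linalg.norm(c - prev, axis=1)) for c in clusters]
        best = clusters[int(np.argmin(score))]
    else:
        best = max(clusters, key=len)
    return best + np.array([rs.start, cs.start])


def _entry_side_direction(midpoints: np.ndarray) -> np.ndarray:
    """Unit growth direction: from the outermost ring midpoint inward."""
    d = midpoints[-1] - midpoints[0]  # outer ring first (largest radius)
    n = np.linalg.norm(d)
    if n == 0:
        raise TrackingError("degenerate centreline")
    return d / n


def locate_tip(cluster: np.ndarray, roi: ROI, n_rings: int = 8,
               frame_shape: tuple[int, int] | None = None) -> TipDetection:
    """Tip position and growth direction from ring-chord midpoints.

    Concentric rings centred on the ROI, radii spanning [0.5, 1.0] of
    the half-size from the ROI edge inward; each ring's intersection
    with the cluster gives a chord whose midpoint lies on the local
    centreline.  A least-squares line through the midpoints is the
    centreline; the tube enters the ROI through its edge, so the tip is
    the cluster extreme along the centreline away from the entry side
    and the direction points from entry to tip.
    """
    if len(cluster) == 0:
        return TipDetection()
    roi = roi.clamped(frame_shape) if frame_shape else roi
    center = np.asarray(roi.center, dtype=float)
    radii = np.linspace(1.0, 0.5, n_rings) * roi.half_size
    dist = np.linalg.norm(cluster - center, axis=1)
    band = 1.25  # ring half-thickness, px
    midpoints, weights = [], []
    for r in radii:
        on_ring = cluster[np.abs(dist - r) <= band]
        if len(on_ring) == 0:
            continue
        # median midpoint of the chord is robust to fringe pixels
        midpoints.append(np.median(on_ring, axis=0))
        weights.append(len(on_ring))
    if len(midpoints) < 2:
        return TipDetection()
    midpoints = np.asarray(midpoints)
    weights = np.sqrt(np.asarray(weights, dtype=float))
    # weighted total least squares via the principal axis of the midpoints
    mean = np.average(midpoints, axis=0, weights=weights)
    centred = midpoints - mean
    _, _, vt = np.linalg.svd(centred * weights[:, None], full_matrices=False)
    axis = vt[0]
    entry_dir = _entry_side_direction(midpoints)
    if np.dot(axis, entry_dir) < 0:
        axis = -axis
    # sub-pixel tip: mean of the furthest few cluster points along the axis
    proj = (cluster - mean) @ axis
    order = np.argsort(proj)[-3:]
    tip = cluster[order].mean(axis=0)
    resid = np.linalg.norm(centred - np.outer(centred @ axis, axis), axis=1)
    confidence = float(1.0 / (1.0 + resid.mean()))
    # direction over the longest available baseline: centreline centroid
    # to the tip (the fitted axis resolves only the orientation sign)
    d = tip - mean
    if np.linalg.norm(d) > 2.0:
        d = d / np.linalg.norm(d)
    else:
        d = axis
    direction = float(np.degrees(np.arctan2(-d[0], d[1])))
    return TipDetection(position=(float(tip[0]), float(tip[1])),
                        direction_deg=direction, valid=True,
                        confidence=confidence)


def validate_detection(
    new: TipDetection,
    history: list[TipDetection],
    roi: ROI,
    max_step_px: float = 20.0,
    max_turn_deg: float = 45.0,
    confidence_floor: float = 0.1,
    frame_shape: tuple[int, int] | None = None,
) -> tuple[bool, ROI]:
    """Accept/reject a detection against the track history.

    First valid detection is accepted if its confidence clears the
    floor; later ones are rejected on jumps larger than ``max_step_px``
    or heading changes above ``max_turn_deg``.  When invalid frames
    separate the new detection from the last accepted one, the step
    allowance grows with the gap (up to 3x) so a short dropout cannot
    deadlock the track.  On acceptance the ROI re-centres at the tip
    (clamped into the frame); on rejection it is returned unchanged.
    """
    if not new.valid or new.confidence < confidence_floor:
        return False, roi
    last = None
    gap = 1
    for back, h in enumerate(reversed(history)):
        if h.valid:
            last = h
            gap = back + 1
            break
    if last is not None:
        step = float(np.hypot(new.position[0] - last.position[0],
                              new.position[1] - last.position[1]))
        turn = abs((new.direction_deg - last.direction_deg + 180) % 360 - 180)
        if step > max_step_px * min(gap, 3) or turn > max_turn_deg:
            return False, roi
    updated = ROI(new.position, roi.half_size)
    if frame_shape is not None:
        updated = updated.clamped(frame_shape)
    return True, updated


@dataclass
class FluorescenceTipTracker:
    """Stateful per-frame tip tracker (preprocess -> segment -> locate ->
    validate -> ROI update)."""

    roi: ROI
    gaussian_sigma: float = 1.0
    median_width: int = 3
    block_size: int = 31
    offset: float = 2.0
    dbscan_eps: float = 3.0
    dbscan_min_samples: int = 8
    max_step_px: float = 20.0
    max_turn_deg: float = 45.0
    history: list[TipDetection] = field(default_factory=list)

    def track(self, frame: Frame) -> TipDetection:
        pre = preprocess(frame, self.gaussian_sigma, self.median_width)
        # the ROI centre is the prior before any valid detection exists
        prev = next((h.position for h in reversed(self.history) if h.valid),
                    self.roi.center)
        cluster = segment_tip_region(
            pre, self.roi, self.block_size, self.offset, self.dbscan_eps,
            self.dbscan_min_samples, previous_tip=prev)
        det = locate_tip(cluster, self.roi, frame_shape=frame.image.shape)
        ok, self.roi = validate_detection(
            det, self.history, self.roi, self.max_step_px, self.max_turn_deg,
            frame_shape=frame.image.shape)
        det = det if ok else replace(det, valid=False)
        self.history.append(det)
        return det


# ---------------------------------------------------------------------------
# interface pipeline
# ---------------------------------------------------------------------------


def _histogram_stretch(img: np.ndarray) -> np.ndarray:
    """Shape-adaptive contrast stretch.

    A strongly bimodal histogram (distinct streams) gets a tight
    percentile stretch to sharpen the transitions; a flat histogram is
    stretched gently to avoid amplifying noise.
    """
    lo_p, hi_p = 1.0, 99.0
    hist, _ = np.histogram(img, bins=64)
    frac = hist / max(hist.sum(), 1)
    # bimodality proxy: mass concentrated in the top two modes
    top2 = np.sort(frac)[-2:].sum()
    if top2 > 0.4:
        lo_p, hi_p = 5.0, 95.0
    lo, hi = np.percentile(img, [lo_p, hi_p])
    if hi <= lo:
        return np.zeros_like(img)
    # rescale without saturating: clipping would flatten the bright half
    # of each interface transition and bias its gradient ridge
    return (img - lo) / (hi - lo)


def detect_interfaces(
    frame: Frame,
    pyramid_levels: int = 3,
    block_size: int = 31,
    dbscan_eps: float = 2.0,
    dbscan_min_samples: int = 5,
    n_samples: int = 20,
    seed: int = 0,
    min_aspect: float = 10.0,
    exclude_mask: np.ndarray | None = None,
) -> list[InterfaceCurve]:
    """Interface curves between co-flowing streams, multi-scale.

    Pipeline: histogram-shape contrast stretch; image pyramid of
    ``pyramid_levels``; adaptive local-mean threshold per level;
    upsample and combine by pixel-majority vote; boundary pixels of the
    combined segmentation; DBSCAN; keep clusters elongated along the
    streamwise axis; reduce each to ``n_samples`` seeded random points
    sorted streamwise.  Curves are returned ordered top-to-bottom
    (decreasing normalized lateral position m).  ``exclude_mask`` masks
    pixels that belong to the tube, whose edges are not interfaces.
    """
    img = _histogram_stretch(frame.image)
    if np.ptp(img) == 0:
        return []
    # edge evidence per pyramid level: adaptive threshold of the local
    # gradient magnitude, upsampled and combined by majority vote
    votes = np.zeros(img.shape)
    level_img = img
    gm0 = np.hypot(*np.gradient(gaussian(img, sigma=1.5, preserve_range=True)))
    for level in range(pyramid_levels):
        smoothed = gaussian(level_img, sigma=1.5, preserve_range=True)
        gm = np.hypot(*np.gradient(smoothed))
        bs = block_size if block_size % 2 else block_size + 1
        bs = min(bs, (min(gm.shape) // 2) * 2 - 1)
        if bs < 3:
            break
        thr = threshold_local(gm, block_size=bs, method="mean")
        floor = np.mean(gm) + 1.0 * np.std(gm)  # reject flat-noise response
        binary = (gm > thr) & (gm > floor)
        if level > 0:
            binary = resize(binary.astype(float), img.shape, order=0) > 0.5
        votes += binary
        if level < pyramid_levels - 1:
            level_img = block_reduce(level_img, (2, 2), np.mean)
    edges = votes > pyramid_levels / 2.0
    edges[[0, -1], :] = False
    edges[:, [0, -1]] = False
    if exclude_mask is not None:
        edges &= ~ndimage.binary_dilation(exclude_mask, iterations=3)
    pts = np.column_stack(np.nonzero(edges)).astype(float)
    if len(pts) < dbscan_min_samples:
        return []
    labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit(pts).labels_
    rng = np.random.default_rng(seed)
    fragments = []
    for k in range(labels.max() + 1):
        cl = pts[labels == k]
        # thin the edge band to one sub-pixel row per column: the row of
        # peak gradient magnitude (quadratically refined) tracks the
        # ridge crest even when the ridge is asymmetric, as it is for
        # the log-compressed fluorescence response
        cols = np.unique(cl[:, 1])
        thin = []
        for c in cols:
            rows_c = cl[cl[:, 1] == c, 0].astype(int)
            ci = int(c)
            r = rows_c[np.argmax(gm0[rows_c, ci])]
            delta = 0.0
            if 0 < r < gm0.shape[0] - 1:
                denom = gm0[r - 1, ci] - 2 * gm0[r, ci] + gm0[r + 1, ci]
                if denom != 0:
                    delta = float(np.clip(
                        0.5 * (gm0[r - 1, ci] - gm0[r + 1, ci]) / denom,
                        -1, 1))
            thin.append([r + delta, c])
        thin = np.array(thin)
        span_c = np.ptp(thin[:, 1]) + 1.0
        spread_r = max(np.std(thin[:, 0]), 0.5)
        if span_c / spread_r < min_aspect or len(thin) < 3:
            continue
        fragments.append(thin)
    # merge fragments of the same interface (DBSCAN splits a curve across
    # gaps, e.g. where the tube crosses it): lateral proximity merge
    fragments.sort(key=lambda f: np.mean(f[:, 0]))
    merged: list[np.ndarray] = []
    for f in fragments:
        if merged and abs(np.mean(f[:, 0]) - np.mean(merged[-1][:, 0])) \
                < 4 * dbscan_eps:
            merged[-1] = np.vstack([merged[-1], f])
        else:
            merged.append(f)
    curves = []
    for thin in merged:
        if np.ptp(thin[:, 1]) + 1.0 < 0.3 * img.shape[1]:
            continue  # interfaces run along the channel; short stubs are noise
        n_take = min(n_samples, len(thin))
        if n_take < 3:
            continue
        sel = rng.choice(len(thin), size=n_take, replace=False)
        curves.append(InterfaceCurve(thin[sel]))
    curves.sort(key=lambda c: c.mean_lateral)
    return curves


def interface_position_at(
    curve: InterfaceCurve,
    station_px: float,
    wall_positions_px: tuple[float, float],
) -> float:
    """Normalized lateral position of a curve at a streamwise station.

    Linear interpolation along the curve; normalization maps the bottom
    wall (stream-3 side, larger row) to 0 and the top wall to 1, the
    controller's m coordinate.
    """
    cols = curve.points[:, 1]
    if not (cols.min() <= station_px <= cols.max()):
        raise TrackingError(
            f"station {station_px} outside curve extent "
            f"[{cols.min()}, {cols.max()}]")
    row = float(np.interp(station_px, cols, curve.points[:, 0]))
    top, bottom = sorted(wall_positions_px)
    return float((bottom - row) / (bottom - top))
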