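# Methods

`tubesteer` is a software-only re-creation of the automation stack of a
continuous-flow lab-on-a-chip that steers a growing pollen tube (PT) by
holding the interface between co-flowing growth media of different Ca²⁺
content at the tube's tip.  Everything the physical setup does with a
syringe pump, a fluorescence microscope and a real cell is represented
here by a model that can be exercised and tested on a desktop: a
hydrodynamic flow-focusing map, a closed-loop state-space controller, a
reduced-order Ca²⁺ transport solver, two image-tracking pipelines, a
synthetic-microscopy generator with exact ground truth, and
turning-event analysis.  This note records the models, their
assumptions, the defaults that matter, and the design decisions taken
where the problem was genuinely open.

## Flow focusing and the control-side plant

The main channel carries three co-flowing laminar streams fed by four
inlets (f₁ = v₁, f₂ = v₂ + v₃, f₃ = v₄).  At low Reynolds number the
two inter-stream interfaces sit at the cumulative flow fractions, so in
the normalized width coordinate m ∈ [0, 1] (origin at the stream-3
wall):

    m₃ = b₃ f₃,      m₂ = m₃ + b₂ f₂,      ideal device: b₂ = b₃ = 1/TFR

The flow-rate ratio FRR = f₂/TFR sets the middle-stream width and the
asymmetric ratio AFRR = (f₃ + f₂/2)/TFR its centreline; the total flow
rate TFR is held constant so repositioning the interfaces never changes
the pressure or shear on the tube.  `calibrate_linear_model` fits b₂,
b₃ from a measured sweep by through-origin least squares and flags (but
does not refuse) extrapolation beyond the fitted flow range, since the
linear law degrades near the side walls.

The discrete-time plant for control is

    x(k+1) = x(k) + B u(k) + w(k),   B = [[b₃, 0], [b₃−b₂, b₂]]
    y(k)   = x(k) + v(k)

with state x = (m₃, m₂), input u = (Δf₃, −Δf₁) (Δf₂ balances the sum),
process error w and observation (tracker) error v.

## Controller

* **Kalman filter.** Time-varying gain, A = I, process covariance q·I
  (default 1e-5), observation covariance r_obs·I (default 1e-4),
  Joseph-form update.  The PI error is computed against the filtered
  estimate by default (`error_source="estimate"`); the raw observation
  can be selected instead.
* **Target selection.** The interface on the side the tip is growing
  toward is active and its target is the tip's normalized lateral
  position; the other interface is a dummy whose target is its own
  current observation, so it holds station.  A tip growing parallel to
  the flow (within 1°) activates the nearer interface.
* **PI law.** u = kp·e + ki·Σe on the active component only.  Defaults
  kp = 4.5, ki = 0.1 (µL/min per unit position error, per 3 s tick)
  settle a 0.2-width step in ≤ 15 ticks with < 10% overshoot on the
  noiseless twin for b ∈ [0.05, 0.2] (µL/min)⁻¹; the integral adds a
  slow (~1 − ki/kp per tick) unwinding mode, so tolerance-level
  settling after saturation episodes takes a few hundred ticks.
* **Constraints.** Candidate flows are projected (Euclidean) onto
  {f₁, f₃ ≥ 0, f₁ + f₃ ≤ TFR}, which with f₂ = TFR − f₁ − f₃ enforces
  0 ≤ fᵢ ≤ TFR and the exact sum.  Anti-windup is by conditional
  integration: the integral is frozen only while integrating would push
  the command further into saturation, so the loop can always unwind
  out of a constraint (a plain freeze deadlocks at the boundary).
* **Exact conservation.** Flows are carried internally as integer
  multiples of TFR/2⁴⁰ (≈ 1e-11 µL/min resolution).  All the resulting
  dyadic floats are exact in double precision, so f₁+f₂+f₃ == TFR
  bit-exactly at every tick of every simulation.
* **Reachability.** With single-interface control f₁ is fixed, so
  moving m₃ re-routes flow between f₃ and f₂ while m₂ = m₃ + b₂f₂ must
  stay inside the channel; the largest reachable m₃ step from m_lo is
  b₃(1 − m_lo)/b₂.  For strongly unequal coefficients (b₂ ≫ b₃) parts
  of the channel are unreachable for *any* gain choice — a structural
  property of constant-TFR single-input control, respected by the test
  sweeps.
* State clipping to [0, 1] in the plant is logged, never silent.

## Reduced-order Ca²⁺ transport

The reference scenario is a 500 µm × 35 µm main channel, a 17 µm
diameter, 250 µm long tube at mid-height with its tip 900 µm downstream
of the junction, streams of 0.13 mM (middle) and 20 mM (sides) Ca²⁺ at
FRR 0.33 / AFRR 0.5 / TFR 10 µL/min, and D = 1.3×10⁻⁹ m²/s.  The
channel width is configurable (it is a device-specific quantity);
acceptance scenarios state it explicitly.

The 3-D problem is reduced to 2-D (streamwise × lateral) in two stages:

1. **Velocity: depth-averaged Stokes–Brinkman.**  µ∇²V − α V = ∇p with
   ∇·V = 0 on a staggered (MAC) grid; α = 12µ/h² is the Hele-Shaw depth
   friction.  The tube blocks only 17/35 of the depth, so it is a
   porous strip, not a solid wall: its friction follows the cubic
   conductance of the two open gap layers (α_strip = 12µh/Σg³, ≈ 29×
   the open-channel value at mid-height placement) and a fraction
   Σg/h ≈ 0.51 of the depth stays open to lateral diffusion.  The
   in-plane viscous term resolves the ~h/√12 ≈ 10 µm boundary layers of
   slow fluid flanking the strip.  The inlet is plug (the
   depth-averaged limit for a channel ~14× wider than deep; lateral
   wall layers can be resolved with `side_wall_noslip`), the outlet has
   prescribed pressure, and face velocities are scaled so the
   volumetric flux equals TFR exactly.
2. **Concentration: upwind finite volume.**  First-order upwind
   convection and central diffusion on the conservative face
   velocities; inlet bands are area-weighted so the discrete interface
   sits at the ideal position; the outlet is purely convective.  The
   steady problem is linear, so the operator is assembled sparse and
   solved directly; the scaled residual of the returned field is
   checked against 1e-5 (the stated convergence criterion) and is at
   direct-solver precision (~1e-14) in practice.  The discretisation is
   an M-matrix, so the maximum principle holds cell-wise.

Default grid: 2 µm lateral × 10 µm streamwise (≈ 30k cells/solve,
seconds per solve on one CPU).  Validation: without the tube the solved
cross-profile matches the two-interface erf similarity solution to
≤ 1% of the concentration range, the error decreases under lateral
refinement, and the advective species flux audit closes to 0.1%.

**Tip difference.**  Δc = c(tip + d/2) − c(tip − d/2), interpolated on
the cross-profile at the tip station (sign positive toward the stream-1
wall); for a linear field this returns exactly gradient × diameter.
`sweep_tip_offset` re-solves with the tube re-positioned to map Δc
against the tip-to-interface offset (the bell curve).

**Known limitation — depth-averaging caps the fidelity of the tip
difference.**  In 3-D, the fluid hugging the no-slip tube surface is
nearly stagnant and exchanges Ca²⁺ around the circumference and
vertically through the gap layers, which strongly homogenises the two
sides of the tip; a depth-averaged model has no such pathway beyond the
reduced-diffusivity strip.  Consequently the 2-D peak Δc in the
reference scenario (≈ 8.4 mM, close to the free-diffusion erf value
across 17 µm at this station) is several-fold larger than full 3-D
simulations of the same scenario produce, and the bell curve's
5%-of-peak half-width lands at ~40 µm rather than ~30 µm.  The
qualitative structure — single peak at zero offset, monotone decay,
bell shape — is reproduced; the acceptance script reports the 2-D
numbers as computed.  Closing the gap would need either the 3-D mesh
this package deliberately avoids or an ad-hoc near-tube mixing closure
with no independent way to fix its coefficient.  The off-centre
interface position in the reference scenario also makes the 2-D bell
~15% asymmetric (the strip diverts flow asymmetrically between the
unequal gaps to either wall); a centred two-stream scenario is
symmetric to < 5% and is what the symmetry test uses.

## Fluorescence calibration and diffusion-coefficient selection

Fluo-3 intensity is log-linear in Ca²⁺ over 2×10⁻³–1 mM:
signal = slope·log₁₀(c) + intercept, fitted by least squares with R²
reported; concentrations outside the linear range are flagged.
`signal_to_concentration` subtracts an illumination baseline and
inverts the line, masking (never silently clipping) non-positive or
out-of-range corrected signals.  `estimate_diffusion_coefficient`
re-solves the no-tube field for each candidate D and picks the smallest
sum-of-squares against a measured cross-profile; ties break toward the
smaller D.

## Tracking

Image convention: row = lateral (row 0 at the stream-1 wall, m = 1),
column = streamwise; directions are degrees, 0° downstream,
counter-clockwise positive.

**Fluorescence tip pipeline.**  Gaussian (σ = 1 px) then median (3 px)
preprocessing; local-mean adaptive threshold (block 31 px, offset 2)
inside an ROI (half-size 40 px); DBSCAN (eps 3 px, min 8) on the
foreground, keeping the cluster nearest the previous tip (the ROI
centre seeds the first frame); 8 concentric rings spanning [0.5, 1.0]
of the ROI half-size intersect the cluster, each chord's median
midpoint lies on the centreline, and a weighted total-least-squares
line through the midpoints gives the axis.  The tip is the mean of the
extreme cluster pixels along the axis; the direction uses the
centroid-to-tip baseline.  Detections jumping > 20 px (scaled up to 3×
across dropout gaps) or turning > 45° per frame are rejected; accepted
tips re-centre the ROI.

**Interface pipeline.**  Histogram-shape-adaptive contrast stretch
(tight percentiles when strongly bimodal, gentle otherwise, no
saturation — clipping would bias the edge), a 3-level image pyramid
with a local-mean adaptive threshold of the gradient magnitude per
level (plus a noise floor), majority-vote combination, DBSCAN (eps 2,
min 5) on the edge pixels, lateral-proximity merging of fragments,
elongation and span filters, and per-column thinning to the sub-pixel
gradient-peak row.  Curves are reduced to 20 seeded random samples, so
results are bit-reproducible.  Because the fluorescence response is
logarithmic in Ca²⁺, the observable intensity ridge of an interface is
offset toward the dim stream from the concentration midpoint; the
synthetic generator logs both rows, and tracking accuracy is assessed
against the intensity ridge (what an intensity-based tracker can see).

**Brightfield fusion tracker.**  Frames are dispatched on a dense
normal-flow statistic: |ΔI|/|∇I| at pixels whose gradient clearly
exceeds the sensor noise floor (robustly estimated from the frame
difference, with the expected noise subtracted from |ΔI|), 95th
percentile within the ROI around the last tip.  Below τ = 1 px/frame
the contour path runs: quantile-thresholded Canny edges, entry-side
border capping, closing and filling, near-convex dark-region selection
(convexity ≥ 0.85, darker than the median background), moment-ellipse
axis, tip = extreme region pixels along the axis away from the entry
side; a near-circular ellipse yields low confidence.  Above τ the
motion path runs: a self-contained per-pixel k-nearest-sample
background model (k = 3, history 50, match distance adapting to ≥ 4.5×
the measured noise), DBSCAN on the foreground, tip = extreme point of
the cluster nearest the last tip along the last heading.  Both paths
share the fluorescence validation rule.

## Synthetic data

The generator is the oracle for every pipeline: frames are rendered
from the same geometry the truth log records.  Fluorescence frames
apply the log-linear calibration to the stream concentrations, smooth
the interfaces with an erf of the stated blur width (default 20 µm,
the diffusion width of the reference scenario at the tip station) and
draw the tube as a bright capsule; brightfield frames are flat with
faint interface ridges (refractive-index visibility) and a dark-halo
tube edge.  Noise is Poisson (2 photons/count) plus Gaussian (sd 2),
seeded and bit-reproducible.  The logged tip is the capsule apex (the
observable tip), not the centreline endpoint.

The virtual tube advances at 12 µm/min (a typical in-vitro lily PT
growth rate; not a measured constant of this device) and turns away
from whichever flank concentration leaves the tolerated band
0.05–0.13 mM, at min(max_turn, κ·tanh(|Δc|/c₀)) deg/min (κ = 60,
c₀ = 1 mM, max 80 deg/min), stopping once its heading points away by
the 30° escape angle.  This response law is deliberately simple and
parameterised — a test harness producing the right qualitative
dose-response (turning more, and more often, with larger |Δc|), not a
biological model; none of its constants are fitted to experimental
turning proportions.  What passing tests show is therefore that the
*software* loop — sensing, estimation, control, tracking, analysis —
behaves correctly on data with known truth; they do not certify
performance on real microscopy, which adds optics (PSF, photobleaching,
debris, streaming) the renderer deliberately omits.

`steering_experiment` runs the closed loop purely in state space (no
rendering) for statistical experiments: the automated mode uses the
Kalman + PI controller on noisy observations (sd 0.01); the "manual"
mode emulates a human operator applying the same target through a
first-order lag of 5 ticks (15 s reaction time) with 0.02 (≈ 10 µm)
positional jitter — the variability automation removes.

## Analysis

Growth direction is the orientation of the trailing secant over a
20 µm arc (unwrapped); a turning event opens when the smoothed heading
moves ≥ 10° from the running reference and the new heading persists
≥ 30 s; angles are unsigned on [0, 180] with the side logged
separately.  The event threshold and persistence are documented
defaults — there is no field-standard operational definition.
Summaries report the turning proportion (experiments with ≥ 1 event)
and first-turn-angle statistics: mean, median, linear-interpolation
quartiles, 1.5-IQR whiskers, outliers, and SD.  Angles are invariant
to global rotation and uniform time rescaling, and summaries to
experiment permutation.

## Problem sizes

Defaults keep everything desktop-scale: transport solves use ~30k
cells (seconds each; the 21-solve offset sweep takes ~1.5 min), the
shipped tracking benchmarks are 50-frame 250×300 px sequences, the
conservation check runs one 10⁵-tick closed-loop simulation, and the
steering statistics use 10–20 seeded replicates per condition.
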