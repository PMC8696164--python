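# Methods

This note documents the models, numerical choices, and open design
decisions behind ocutrack, and what the synthetic-scene tests do and do
not establish about real recordings.

## Imaging model and coordinate conventions

The tracker assumes dark-pupil infrared imaging: the pupil is the darkest
region of the frame, the iris/sclera mid-gray, and the corneal specular
reflections (glints) the brightest.  Frames are single-channel 8-bit
images, typically ≤ 300×300 px.  Coordinates are 0-based with x = column
and y = row, origin at the top-left, pixel centers at integer positions.
Ellipse orientation θ is measured counter-clockwise from +x in image
coordinates and normalized to [0, π); a circle is represented in the same
model type with a = b and θ = 0 so downstream code never branches on
shape.

## Preprocessing

Each frame is Gaussian-smoothed (reflective borders, default σ = 2 px)
and thresholded so the target blob becomes the 1-class.  Smoothing
precedes binarization by design: blurring a 0/1 image would destroy the
binary contract the edge walker relies on.  The automatic threshold
proposal uses Otsu's between-class criterion on the intensity histogram —
the underlying estimator is distribution-based by intent, and Otsu is the
standard reproducible choice — with the inversion flag chosen by which
class the user's seed pixel falls in.  All proposals are starting points;
`threshold`, `invert`, and the σ values are user-overridable, and real
recordings normally need such tuning.  The glint channel has its own
threshold and a lighter default blur (σ = 1 px), because a 2–3 px
specular spot does not survive the pupil channel's smoothing.

## Walk-out contour detection

From a seed inside the blob, rays are cast along the four cardinal axes
plus diagonal directions with integer steps (m, n).  The default set —
sign/swap closure of {(1,1), (1,2), (2,1), (1,3), (3,1), (2,3), (3,2)}
plus cardinals — yields 32 near-uniformly spread directions, the default
contour budget; the closure of {(1,1), (1,2), (1,3), (2,3), (1,4), (3,4),
(1,5), (2,5)} yields a denser 64.  The specific step pairs are this
package's choice, constrained to spread angles evenly.

All rays are gathered in one batched fancy-indexing pass (rays padded to
a common length; padding reads the seed pixel, which is 1 by precondition
and therefore can never look like an edge).  The first 0-pixel along each
ray is the edge; the returned position is the midpoint between the last
1- and first 0-sample along the step, which halves the quantization bias
of either lattice point.  Two consequences are accepted deliberately:

* a ray samples only lattice multiples of its step, so a (1,3) ray sees
  the image every √10 px along its length — thin structures can be
  jumped, and the radial quantization of a contour point is bounded by
  half its step length (≤ √13/2 ≈ 1.8 px for the coarsest default step);
* rays that reach the frame edge without meeting background contribute no
  point.

Correctness of the batched formulation is established by exact,
point-for-point agreement with a naive per-pixel iterative walker on
hundreds of random blobs, not by wall-clock claims.

## Occlusion filter

Given contour points, the filter computes the mean point, each point's
Euclidean distance to it, and the standard deviation of those distances;
points whose distance deviates from the mean distance by more than 1 SD
are discarded in a single pass.  The deviation is two-sided by default:
that is the only reading under which a clean ellipse contour (whose
points are legitimately non-equidistant from the center) stays intact.  A
one-sided variant (discard only far outliers) is available via
`filter_mode="one_sided"`.  Ties at exactly 1 SD are kept, with a ~1e-9
relative tolerance so that a perfectly equidistant set (SD = 0) is never
trimmed by floating-point rounding.  The filter is applied once, not
iterated.

On a clean pupil the rule still discards roughly a third of the points
(their distance spread is smooth, so ±1 SD covers ~68%); this is inherent
to the rule and harmless, since the fits need only 3–5 points.  Against a
90° occluded sector terminated at 60% radius the filter removes the
shortened points and restores sub-pixel center accuracy on constructed
contours.  On *rendered* occluded scenes, rays near the sector boundary
terminate at intermediate radii and can survive the single pass, leaving
a ~1.3–1.6 px center bias pulling toward the occluder — the residual
error the underestimation analysis quantifies.  Fitted area under
occlusion never exceeds the true area, and raising the budget from 32 to
64 rays reduces the area error; this is the mechanism behind the
tracker's inherent tendency to underestimate the pupil outline around
occlusions.

## Shape fits

The ellipse fit is the numerically stable direct least-squares conic fit
with the ellipse-specific constraint (scatter matrix split into quadratic
and linear blocks; one 3×3 eigenproblem), applied to centroid-centered
points for conditioning.  Degenerate inputs (collinear points,
non-elliptical conic, non-positive axes) raise a fit error that the
engine converts into a fallback.  The circle fit is the algebraic Kåsa
least-squares circle.  Both are deterministic; equivariance under
translation and rotation is covered by tests.

## Frame-to-frame policy and blink fallback

The walk-out is re-seeded each frame at the **last accepted** fit center
— not the last attempted — so one bad frame cannot poison the seed.  A
new fit is distrusted when its center jumps more than
`center_jump_frac × (2b_prev)` (default ¼ of the previous minor-axis
length) or its area changes more than 1.5-fold (bounds inclusive).  On
distrust or walk-out failure, a circular Hough transform over the
foreground boundary searches radii within ±40% of the previous mean
radius.  Candidates are scored by the product of three [0, 1] terms, so
any vanishing term vetoes:

* position: `exp(−(d/s)²)` with `s` = ¼ of the frame diagonal — the
  fallback searches the whole frame, so this term ranks candidates by
  proximity without vetoing a lone legitimate re-acquisition far from the
  prior;
* size: `exp(−|log(A/A_prev)|)`;
* fill: fraction of 1-pixels inside the candidate disk.

A candidate needs a minimum Hough accumulator support (0.2 of the
perimeter) and a total score ≥ 0.25.  If none qualifies the frame is a
blink: no pupil, `method="blink"`.  A frame with no pupil/background
contrast at all (e.g. an all-dark frame, which thresholds to
all-foreground) is likewise a blink.  On recovery the frame is logged
with `method="hough_fallback"` using the recovered circle, and the next
frame's walk-out starts from its center.  A full 5-parameter ellipse
Hough was rejected deliberately: the fallback's job is re-seeding, and
the walk-out re-runs from the recovered center anyway.  All fallback
thresholds are this package's quantifications of qualitative notions
("excessive", "most probable", "suitable") and are configurable.

## Engine loop and plug-ins

Per frame: glint detection (8-ray walk-out + circle fit per seed; a seed
off-glint this frame is skipped, not fatal) → glint disks (+1 px margin)
filled to 1 in the pupil transform so rays pass through them → pupil
walk-out → filter → fit → deviation policy → exactly one JSON-serializable
record, delivered to every registered extractor in order as an
independent copy.  Extractor exceptions are logged and swallowed —
acquisition integrity beats experiment-module correctness.  Importers are
plain iterables of frames (in-memory arrays, PNG/TIFF frame directories,
or video files via imageio); delivery is synchronous and in-order, which
makes runs byte-for-byte reproducible.  The JSON field names constitute
this package's log contract (see README); record round-tripping is
lossless.

## Oculometrics

* **Reactivity speeds.**  The pupil-area trace is smoothed by a short
  moving average (default 5 samples; blink gaps are masked, never
  interpolated) and differentiated by central differences.  Within each
  stimulus cycle, samples with dA/dt < 0 pool into constriction and > 0
  into dilation; the per-cycle speed is the mean |dA/dt| of the phase,
  reported positive, and the headline v_c/v_d are medians across cycles
  with quartiles.  Per-cycle means (rather than derivative extrema) were
  chosen as the more noise-robust reading.  At high frame rates the
  pixel-quantized area needs a wider smoothing window (e.g. ~0.3 s) or
  the sign-split means dilute toward each other; the window is a
  parameter.  A paired one-sided Wilcoxon test of v_c > v_d across cycles
  is attached as a convenience.
* **ETM rate.**  An eye-tracking movement is a contiguous run of azimuth
  samples with |dθ/dt| above threshold; events closer than 0.1 s merge.
  The default threshold is 10°/s — twice the commanded 5°/s grating
  slow-phase speed, so slow tracking never triggers; the exact constants
  of the published derivative-thresholding procedure are not reprinted
  anywhere accessible, so these defaults are documented and configurable.
  Azimuth calibration is user-supplied (deg/px); uncalibrated traces are
  analyzed in px/s with units recorded in the output.
* **Grating schedule.**  Eight 30 s trials, 4 s gray gaps, two horizontal
  directions, 0.05 cycles/°, 5°/s — the standard protocol, exposed as a
  timeline builder for synthetic scenarios and experiment extractors.

## Synthetic scenes

The generator rasterizes anti-aliased scenes at 4× supersampling with box
downsampling (so subpixel ground truth is meaningful), at levels pupil 40
< iris/background 150 < glint 250, plus seeded Gaussian pixel noise
(default SD 2 intensity units, a realistic short-exposure CCD figure;
deterministic per (seed, frame)).  Scenarios script the kinematics:

* `static`, `drift` (default 0.15 px/frame, under the jump policy);
* `plr_sine`: area entrained inversely to the sine brightness drive with
  a configurable latency and gain (default 0.3, i.e. ±30% area).  The
  `triangle` waveform makes each period fall for 1/(1+ratio) of the
  period and rise for the rest, so the scripted v_c/v_d equals `ratio`
  exactly — the oracle for asymmetry recovery;
* `okr_sawtooth`: slow phases at the grating speed with `n_fast` scripted
  resets (default 10/min, 0.15 s each).  The reflex-absent variant
  replaces the sawtooth by a band-limited random walk (3 s correlation
  time) rescaled to the same positional SD: a per-frame white-noise walk
  with matched position variance would imply per-sample speeds above the
  ETM threshold, which is not what a reflex-absent eye does — it drifts
  slowly;
* `blink_script`: full-closure interval, then the eye reopens with a
  configurable shift (a large shift exercises the Hough path; a small one
  re-locks by walk-out alone);
* `occluded`: an eyelid-like angular sector covering the pupil beyond
  60% of its radius.

What the scenes do **not** emulate: iris texture, soft eyelid gradients,
whisker motion blur, illumination drift, off-axis corneal distortion, or
head motion.  Passing tests therefore establish algorithmic correctness
and the contracts above, not performance on degraded real footage — on
real video the thresholds, σ, and ray budget need per-setup tuning, and
heavy obstruction remains the known failure mode of edge-based tracking.

## Problem sizes and determinism

The test suite runs the engine on scenes of 96×96–96×128 px at 10–300
frames and the analyses on 30–60 s traces at 60 Hz — sizes chosen so the
full suite completes in well under a minute while every contract is
exercised end-to-end.  All randomness (scene noise, random blobs,
reflex-absent walks) flows from explicit integer seeds; engine runs are
byte-identical across repetitions by construction.
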