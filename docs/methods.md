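# Methods

`pushtrack` reconstructs sprint and skeleton push-start step
characteristics and mass-centre velocities from multi-camera body-part
segmentation masks. This note records the models the package implements,
the parameters that matter, what the synthetic scene generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinate conventions

World frame: right-handed, X along the direction of travel, Z up, ground
at Z = 0. Camera frame: x right, y down, z along the optical axis, so
pixel origin is top-left with y increasing downwards. Frames are 0-based;
time = frame / fps; all lengths in metres, times in seconds. The nominal
sampling rate is 200 Hz, frame-locked across cameras.

## Camera geometry

Cameras are standard pinhole models with optional 5-coefficient Brown
radial–tangential distortion (zero by default: the synthetic scenes are
distortion-free). Calibration is an *input* — a JSON document validated
on load — not something the package estimates; bundle adjustment and
intrinsic calibration are upstream concerns.

Triangulation is linear DLT on undistorted normalised coordinates
followed by Levenberg–Marquardt reprojection refinement (on by default).
The DLT condition number attaches an ill-conditioned warning above 1e6.
Rigid alignment between coordinate systems is orthogonal Procrustes
(Kabsch) without scale — both systems are metric; a similarity variant
exists behind a flag for diagnostics. All standard deviations reported
anywhere in the package are sample SDs (N−1).

## Occupancy mapping and footfall candidates

The ground plane is divided into 0.05 m cells. For each cell and each of
three probe heights — ground (centred `ground_offset` above Z = 0,
default 0.025 m), knee (0.5 m) and body (1.0 m), each a 0.05 m thick
band — the probe volume is projected into every camera and scored by the
fraction of the projected region's pixels that are foreground (any
nonzero part label). The projected region is approximated by the
axis-aligned bounding rectangle of its eight projected corners and
evaluated with a summed-area table restricted to the foreground bounding
box, which keeps a full-grid sweep at 200 Hz tractable. The cell value
is the *mean* of per-camera scores over cameras whose projection lies
fully inside the image: a mean rather than a sum keeps values in [0, 1]
and makes thresholds independent of camera count (the alternative
reading, accumulation by summing, is a config switch away by scaling the
threshold).

The raised ground band exists because a low sled running beside the
athlete can clip rays from ground-level probes to the cameras on the
sled's side; lifting the probe band 0.025 m restores those views. For
unobstructed sprinting `ground_offset` can be set to 0.

Footfall detection: cells at or above the detection threshold (0.5) are
merged 8-connectedly and each blob contributes one peak (ties toward the
smaller X then Y index). A peak is verified when occupancy of at least
the verification threshold (0.3) exists within 0.5 m at knee height
*and* within 1.0 m at body height — isolated ground-level blobs with no
leg or torso above them are discarded. Verified peaks are linked over
time into runs: a peak continues a run when its occupancy-weighted
location is within 0.30 m of the run's last location, with up to 3
missed frames tolerated. The weighted location is used because the
argmax of a flat-topped foot-sized blob wanders across the foot from
frame to frame. Runs shorter than 5 frames (25 ms) are flickers and are
dropped. Each surviving run is a contact candidate; its anchor frame is
the centre of the (moving-average smoothed) occupancy maximum, which
falls near mid-stance.

## Touchdown / toe-off refinement

Each candidate is refined in image space:

1. **Foot box.** A 0.30 × 0.15 × 0.12 m box, long axis along X and floor
   on the ground, is initialised at the candidate location. Its ground-
   plane centre is optimised by coordinate descent (step 0.01 m, halved
   on failure, stop at 1e-3 m) maximising the mean over cameras of the
   fraction of the projected rectangle covered by foot-labelled pixels.
   Because the box is deliberately larger than a foot that objective is
   flat over small translations, so the centre is then pinned by
   triangulating the per-view centroids of the winning foot label inside
   the fitted projection, with two corrections: the *silhouette bias*
   (the centroid of a convex body's projection is not the projection of
   its centre) is estimated on the box itself and subtracted, and views
   whose centroid disagrees with the multi-view consensus (partial
   occlusion by the shank, the contralateral swing leg or the sled) are
   rejected and the rest re-triangulated. The majority foot label inside
   the final projection decides the side. On clean single-foot fixtures
   the fitted centre lands within 0.01 m of truth; in full scenes the
   absolute position keeps a small forward offset (the shank hides part
   of the heel everywhere), which cancels in step lengths.

2. **Slice profiles.** The box is projected into each view (rect padded
   6 px vertically only, so a lifting foot stays in view without
   diluting the end slices) and split into up to 8 equal-width vertical
   slices ordered heel → toe by world X. Views resolving the foot at
   fewer than ~2 px per slice reduce their slice count (minimum 3);
   views below 6 px are excluded. Each slice is reduced to two 1D
   columns: the horizontal mean of the (foot-label) intensity and of its
   3 × 3 Sobel vertical gradient. On real imagery the same operator runs
   on grayscale intensity (config switch); the synthetic path profiles
   the label masks because they carry no photometric texture.

3. **Displacement.** The vertical displacement of a slice between two
   frames is the integer shift in ±15 px minimising the joint SSD of the
   intensity and gradient columns, refined by a parabola fit (ties break
   toward the smaller magnitude). A match is *unreliable* — reported as
   zero displacement with a flag — when both columns are flat, when the
   best shift is clamped at the search boundary, or when the content
   mass changes more than fourfold (the foot appearing or vanishing is
   not motion). For event detection each frame is matched directly
   against the mid-stance anchor profile; chaining frame-to-frame
   offsets is also available (`track_slices`) but lets correlated
   segmentation-boundary jitter accumulate into spurious displacement.

4. **Events.** Scanning outward from the anchor, the first frame whose
   toe-end slice (forwards) or heel-end slice (backwards) shows
   |displacement| > 2 px — confirmed by the next clean frame, and with
   at most a 6 px/frame change so isolated mismatches cannot fire —
   marks movement. The displacement ramp is extrapolated linearly back
   to zero through the two frames bracketing the crossing: that zero
   crossing estimates the frame at which the slice *started* to move,
   removing the threshold-crossing lag. "End slice" means the outermost
   slice actually containing foot content at the anchor. Onsets further
   than 40 ms from the candidate's own first/last frame are rejected as
   unreliable views (an occlusion edge sweeping across a stationary foot
   mimics motion mid-stance). Cameras fuse by the median, half-frame
   ties rounding toward mid-stance; with no acceptable onset the
   candidate boundary is used and flagged, and such events are excluded
   from step pairing, as are events whose stance touches the capture
   window edge. On the noiseless synthetic suite every fully observed
   step's touchdown and toe-off land within 0.9 frames of truth at
   200 Hz; under ±2 px boundary noise timing degrades to a few frames
   while step-averaged velocities remain accurate.

## Mass-centre tracking

Athlete: per camera, tight 2D boxes around the head and torso labels
(largest blob wins when split, flagged when the runner-up is comparable;
confidence scales with pixel count). A 3D box per part (defaults: torso
0.35 × 0.35 × 0.55 m, head 0.20 × 0.20 × 0.25 m) is initialised from the
triangulated 2D box centres — snapped to the nearest body-height
occupancy peak when one is within a metre — and optimised by coordinate
descent over centre and size (size bounded to ±30% of defaults)
maximising the mean rect-IoU between the projected box's bounding
rectangle and the observed 2D boxes. The bounding-rectangle IoU is a
documented speed approximation of exact hull overlap. Subsequent frames
warm-start from the previous pose; a mean IoU below 0.1, fewer than two
views, or no body-height occupancy support within a metre marks the
frame lost and the track re-initialises. The CoM proxy is the weighted
average of the two centres, weights 0.14 head / 0.86 torso — the
approximate head and trunk shares of the segmental masses they stand in
for; both weights are configuration, and frames missing one part fall
back to the other with a flag.

Sled: a rigid template (default a 0.9 × 0.5 m corner rectangle) whose
corners arrive as per-camera 2D detections with confidences. Detections
below confidence 0.5 are gated out; corners seen by ≥ 2 cameras are
triangulated, and with ≥ 3 corners the pose is solved by Procrustes
against the template. The centroid of the template corners — the mass
centre of a rigid object with uniformly distributed mass — is mapped
through the pose. Fewer than 3 corners leave the frame invalid.

Both centroid series pass through a bi-directional Kalman filter:
per-axis constant-velocity model with white-noise acceleration (spectral
density 5 (m/s²)²·s, tolerant of the ~10 m/s² accelerations of a sprint
start), measurement SD 0.03 m (box-centre jitter), and an outlier gate
at the χ²(3 dof) 99th percentile of the joint innovation Mahalanobis
distance; gated or missing frames are bridged by prediction, and a
Rauch–Tung–Striebel backward pass completes the smoother. The filter
state initialises from the first two valid positions, so an exactly
constant-velocity input is reproduced exactly; with the process noise
driven to zero and a diffuse prior the smoother reproduces the batch
least-squares line fit, which the tests use as an independent oracle.
Velocities are finite central differences of the smoothed positions
(one-sided and flagged at the ends), exact for linear and quadratic
trajectories.

## Step characteristics

A step runs from one touchdown to the contralateral touchdown: GCT is
the leading foot's stance time, FT the gap to the next touchdown,
ST = GCT + FT, SL the world-X distance between touchdown locations
(the track-aligned axis makes travel-axis and resultant distance
equivalent to first order, and X-only is robust to lateral foot
placement), SF = 1/ST and SV = SL/ST — identities that hold to machine
precision by construction, and step lengths telescope to the first-to-
last touchdown displacement. Same-foot consecutive events or overlapping
stances raise a sequence error naming the offending pair; the pipeline
falls back to the longest alternating non-overlapping chain and logs the
rejection. Step-averaged CoM and sled velocities are means of the valid
per-frame X velocities in [TD_i, TD_{i+1}). A step belongs to its
leading foot; for pushing, the leg on the declared sled side is *inside*
and the contralateral *outside*, and sprint trials map the declared
push side onto corresponding roles so paired comparisons align across
activities. Per-athlete within-role means feed the estimation
statistics; athletes missing a role are excluded with a log entry.

## Agreement and estimation statistics

Between-system agreement is Bland–Altman: bias = mean(test − criterion),
sample SD of differences, 95% limits bias ± 1.96 SD, plus the OLS R² of
test on criterion (undefined, flagged, for a constant criterion). The
published agreement tables print a single "95% LoA" column that equals
bias + 1.96·SD (the upper limit) for most rows at printed precision;
both limits are computed here and the upper one is what the table
reproduction checks.

Paired comparisons use paired Cohen's d, by default the mean difference
over the SD of the differences (the average-SD variant is available and
the choice is recorded); identical samples give d = 0, and zero
dispersion with a nonzero mean is an error. The 95% CI is a BCa
bootstrap over resampled pairs (default 5000 resamples): bias correction
z₀ from the fraction of resampled statistics below the observed value,
acceleration from jackknife skewness, with a flagged fall-back to the
percentile interval when the resample distribution degenerates. P-values
come from a sign-flip permutation test (paired design — each reshuffle
negates each within-pair difference), with exact enumeration of all 2^N
sign patterns when 2^N does not exceed the requested reshuffles, and a
+1 continuity correction otherwise; all-zero differences give p = 1.
Effects are read as small/moderate/large at |d| ≥ 0.2/0.5/0.8. A
minimal Gardner–Altman-style estimation plot is available when
matplotlib is installed.

A calibration caveat the tests make explicit: at n = 12 pairs the BCa
interval for a mean empirically covers ~90–91% at nominal 95% (scipy's
independent BCa implementation gives the same number on identical
datasets) — the familiar small-sample undercoverage of percentile-family
intervals. Consumers comparing small paired samples should read the CI
accordingly.

## Synthetic scenes

The generator exists so the whole chain is testable without cameras or a
segmentation network; its defaults are the working conditions of the
tests and the acceptance study.

*Gait.* Forward motion follows the monoexponential sprint-acceleration
model v(t) = v_max(1 − e^(−t/τ)) from the block (defaults v_max 8 m/s,
τ 1.2 s); a trial's capture window opens `start_offset` seconds into the
acceleration, emulating staggered start lines. Touchdown times are
solved so each step's CoM displacement equals the local step-length
target v(TD)/f₀ (f₀ = 4 Hz) scaled by per-leg multipliers, which makes
configured asymmetries appear in the truth tables by construction;
ground contact occupies 45% of each step. Contact locations advance by
exactly those targets, the first placed under the CoM at mid-stance.
Stance feet are exactly stationary; swing feet travel on a raised-cosine
path with sinusoidal lift peaking at 0.45 m (a realistic sprint ankle
peak — this also sets the vertical velocity at touchdown/toe-off, ~3.5
m/s, hence how sharply events are detectable). The CoM runs at 0.55 ×
stature upright (rising from a crouch) or 0.7 × 0.55 × stature bent over
when pushing. The sled, when present, is a 1.0 × 0.55 × 0.15 m cuboid
0.75 m beside and 0.3 m ahead of the athlete on the declared side; its
four template corners are emitted as 2D detections with confidence 1,
dropped to 0.2 when a body segment occludes the camera ray.

*Rendering.* The body is labelled convex primitives — head sphere, torso
capsule, two-link legs with knees from planar IK, cuboid feet, cosmetic
arms (the sled-side hand rides the sled handle) — rasterised far-to-near
in painter's order at 960 × 540 (half the native sensor resolution, for
desk-scale runtime; pixel-level accuracies roughly halve at full HD).
Painter's order by primitive centre depth is adequate for convex, rarely
interpenetrating bodies; it is not a z-buffer and mutually
interpenetrating primitives would resolve arbitrarily. The sled is
painted as *background*, reproducing the property that part segmentation
never labels the sled as foreground — it occludes but never detects.
Masks render lazily per (camera, frame), so long sequences never occupy
memory.

*Corruption.* Per camera-frame, deterministically seeded by (seed,
camera, frame) so results are independent of access order: whole-mask
erosion/dilation by a random ±k px (the boundary-noise condition),
whole-frame dropout with probability p, and spurious part-labelled salt
blobs.

*What it does not emulate:* photometric texture (so the slice tracker's
grayscale path is exercised only on constructed fixtures), soft tissue
and clothing motion, motion blur, rolling shutter, lens distortion,
calibration error, and the correlated, structured failure modes of real
segmentation networks. Passing the synthetic suite therefore
demonstrates the geometry, detection logic and statistics are correct
under known imaging, not that a particular CNN's output would be this
clean.

## Accuracy study (what the acceptance script runs)

Five pushing trials (offsets 0.6/0.9/1.4/2.0/3.0 s, ~8 m each, ~1700
frames total per condition) are simulated, rendered, and pushed through
the full pipeline; detected events are matched to truth contacts by
stance location, and only stances fully inside the capture window are
scored. Noiseless: 23 comparable steps, touchdown and toe-off within 0.9
frames of truth on every step, step-length error +4.5 ± 9.6 mm. With
±2 px boundary noise: step-averaged athlete CoM velocity error SD
~0.03 m/s and sled velocity error SD ~0.01 m/s. The noiseless half is
fully deterministic (the gait model is noise-free); the noisy half and
the statistics calibration consume the run seed. These numbers are
recomputed from scratch by `scripts/acceptance.py`.

## Known limitations

- Absolute foot positions carry a small forward bias (shank occlusion of
  the heel); step lengths are unaffected but absolute contact maps would
  inherit it.
- Event timing under heavy boundary noise degrades to a few frames; the
  step windows remain good enough for step-averaged velocities.
- The first and last contacts of a capture window cannot be timed (their
  stance is not fully observed) and are excluded from steps.
- The IoU used for body-box fitting is on bounding rectangles, not exact
  projected hulls.
- BCa small-sample undercoverage, as noted above.
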