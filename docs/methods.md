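# Methods

`gazefish` reconstructs the 3D gaze of freely swimming fish from calibrated
camera views and tracked body poses, and renders what a fish's eye sees.
This note documents the models, the parameters that matter, and the limits
of what the synthetic validation shows.

## Eye model and gaze geometry

The eyeball is modeled as a sphere of diameter equal to the fish's eye
diameter (goldfish average 6.75 mm), centered one eye radius beneath the
sclera anchor on the body mesh. The visible sclera is the light disk around
the anchor; the pupil is a dark cap on the sphere surface. The gaze ray
starts at the retina center — taken to be the sphere center, i.e. one eye
radius beneath the surface — and points through the 3D pupil center.

In a fronto-parallel view of the eye, a pupil at normalized offset
`o = (pupil center − sclera center) / sclera diameter` sits at spherical
angle `asin(2|o|)` off the eye's optical axis; `|o| ≤ 0.5` by construction.
The normalized eye-movement scalar used in the behavioral analysis is the
anteroposterior component of `o`, signed through the eye side (anterior
displacement of the left eye positive, of the right eye negative), so a
gaze swinging toward the fish's left is positive for either eye.

## Pose-conditioned rectification

A fixed camera rarely views an eye square-on, so the eye region is
rectified before detection. A square patch of side 3 × eye diameter,
tangent to the head at the eye anchor and axis-aligned with the local
anteroposterior/dorsoventral directions, is projected twice: in the current
pose, and after virtually rotating the fish about the anchor until the
patch is parallel to the image plane. The homography H between the two
projected quadrilaterals (normalized direct linear transform; bottom-right
entry fixed to 1) maps the raw image onto a fronto-parallel crop with a
known metric scale. Detected pixel coordinates are carried back through
H⁻¹ and ray-cast from the camera onto the eye sphere (nearest
intersection), which is exact — no small-angle approximation — and
accounts for the pupil lying off the tangent plane.

An eye is considered visible when its outward optical axis faces the
camera (negative dot product with the viewing ray); grazing and averted
views raise a per-frame error and the frame is skipped, never imputed.

## Detection

Detection is deliberately classical and deterministic:

* **Sclera.** The crop has up to three intensity modes (pupil, background,
  sclera). Threshold candidates come from 3-class multi-Otsu (upper
  threshold) and plain Otsu, nudged half a gray level to avoid plateau
  ties; the first threshold whose largest bright connected component is
  plausible (≥ 50 px², ≤ 60 % of the crop) seeds the detection. The
  component's filled centroid and area-equivalent diameter initialize a
  sub-pixel refinement: the iso-contour at the half-contrast level between
  background and sclera brightness is extracted and fit with a trimmed
  algebraic (Kåsa) circle fit. For a Gaussian-blurred edge the
  half-contrast crossing coincides with the true edge even under the
  anisotropic blur left by rectifying a tilted image, which is what makes
  sub-pixel accuracy possible. Contour stretches adjacent to the pupil are
  excluded from the fit (the two blurred boundaries merge there and would
  notch the rim); the exclusion zone comes from a crude darkest-decile
  pupil estimate and is re-derived once from the refined circle. An
  externally supplied sclera mask bypasses thresholding entirely.
* **Pupil.** Inside the sclera circle, the darkest decile of intensities
  seeds the blob (largest area; ties broken by lowest mean intensity, then
  proximity to the sclera center). Blobs confined to the outer 20 % rim
  band are rejected as boundary bleed. The blob is re-segmented at the
  half-contrast level between its core and the sclera brightness and
  refined with the same contour fit, with points near the sclera rim
  excluded.
* **Tracking a crop** runs two rounds: detect both disks, then refit each
  with the other's blur zone excluded. This removes the mutual bias where
  pupil and sclera boundaries meet, which dominates the error for
  rim-adjacent (edge-case) pupils.

Centers, not diameters, drive the science: gaze needs the pupil center and
the sclera center/diameter ratio; position errors are reported in mm by
scaling the *detected* sclera diameter to the 6.75 mm average eye diameter.

Key tunables: sclera `min_area` (50 px²), pupil seed quantile (0.10),
contour exclusion margin (0.18 sclera radii ≈ 2 blur sigmas at the
validation scale), edge/center split threshold on `|o|` (0.20). Thresholds
were chosen for backlit/synthetic imagery and are arguments, not
constants, because real recordings will need retuning.

## Synthesized eye images (validation ground truth)

The generator reproduces the validation recipe exactly: a w × w square
filled with a background gray; a light sclera disk of diameter 2w/3 at the
center; a dark pupil with radius uniform in [w/6 − w/20, w/6 + w/20] px
and center uniform in [w/2 − w/6, w/2 + w/6] px per axis, resampled until
fully inside the sclera; a perspective tilt; Gaussian blur with kernel
w/6 (rounded to odd; σ from the usual 3σ-support convention,
σ = 0.3·((k−1)/2 − 1) + 0.8); and single white noise pixels at 0.05 % of
the pixel count, sampled without replacement.

Unstated details were fixed once as follows: the tilt is a rotation of the
image plane about its own center (yaw and roll each uniform in ±30°) seen
by a virtual camera at distance 2w, so the eye stays in frame at any tilt;
disk intensities are background +60 (sclera) and −80 (pupil) on an 8-bit
scale with background 128. All are configurable.

The validation harness rectifies each image with the known tilt inverse —
standing in for the pose-derived homography — detects, and scores against
the pre-tilt truth. View-angle error is the 3D angle between detected and
true gaze directions under the orthographic eye-sphere model; the signed
variant (difference of polar angles) is also reported for mean/SD
summaries.

## Synthetic scenes

`synthesize_scene` builds a deterministic two-fish flow-tank recording:
ellipsoidal fish bodies (length 0.12 m) deformed by linear blend skinning
along a 5-bone anteroposterior skeleton (yaw-only bending with slight
roll; pitch is structurally forbidden), holding station against a
1.4 BL/s flow inside the 0.88 × 0.25 × 0.25 m arena. The leader swims
0.21 m ahead, offset 0.065 m to the follower's right, weaving ±0.04 m
laterally and bobbing ±0.02 m vertically; the follower's heading
oscillates ±8° in yaw with ±2° of body roll and a small station-keeping
jitter. These magnitudes were chosen to look like station-holding
schooling at ~90 fps while keeping the leader inside the follower's
right-eye oculomotor range. Under "fixating" behavior each pupil is placed
on the eye sphere so the gaze passes through the neighbor's centroid,
clamped at 85° of excursion (the sclera rim); "static" pins the pupil to
the sclera center and "random" draws admissible pupil positions uniformly.

Two virtual cameras mimic the recording geometry: a backlit bottom view
(binary silhouettes) and a side view placed along the follower's right-eye
optical axis (60° off the heading) so that eye is imaged nearly face-on,
as the view used for eye tracking should be. The side renderer draws
flat-shaded silhouettes, the eye-sphere outline as the sclera disk, and
the pupil as the *foreshortened ellipse* of the spherical cap (minor axis
scaled by the cosine of the viewing angle) — without the foreshortening a
flat pupil disk clips against the sclera rim at large excursions and
biases the detected centroid inward by several degrees.

What the scenes do not emulate: body texture, lighting, water optics
(refraction at tank walls), occlusions between fish, pupil foreshortening
in the *synthesized-image* benchmark (which follows the published recipe
instead), and pose-estimation error — poses are inputs here, so
end-to-end results bound detection and geometry errors only, not the full
video pipeline.

## Retinal view

The retinal camera sits at the gaze origin with its optical axis along the
gaze, up vector the fish's dorsal axis projected orthogonal to the axis,
and a 190° field of view (goldfish). The projection is the equidistant
fisheye model, r = image_radius · θ / (fov/2) (default image radius
256 px): radially monotone, azimuth-preserving, and invertible over the
full field, which a pinhole model cannot cover. With the two eye axes at
±60° azimuth from the heading, 190° per eye leaves exactly a 50° un-imaged
sector behind the fish. Neighbor position on the retina is the centroid of
visible projected mesh vertices; silhouette rasters use painter's order on
triangle centroid distance (adequate for two convex-ish bodies; no
z-buffer).

## Behavioral statistics

The position angle `a` is the signed horizontal bearing of the leader in
the follower's local frame. Published accounts of its sign are
inconsistent; here the *default* is positive-right with a
`convention="left-positive"` flag, and every downstream result is
convention-parameterized. Under the left-positive convention the fixation
geometry predicts the observed structure directly: for right-eye data the
normalized eye movement is ≈ −sin(60° − |a|)/2, a negative, near-linear
trend of eye movement on position angle. The synthetic scenes reproduce it
(r ≈ −0.87 end-to-end) with both the slope sign and the ±0.4 eye-movement
range matching the real-data figures.

Filters are strict inequalities as published: recording-quality frames
need an x–z plane angle ≤ 40° and ≥ 0.2 m x-separation, with surviving
segments of at least 40 consecutive frames; leader-follower frames need
|a| < 40°, |x| < 0.4 m, d < 0.45 m. Both filters are idempotent.

Bootstraps follow the stated protocols: the regression bootstrap draws
3000 points with replacement from each side stratum (x < 0 vs x ≥ 0 on the
eye-movement variable by default; `strata_on="a"` is provided because the
left/right asymmetry being compensated lives in the position angle) and
fits OLS on each 6000-point batch for 200 iterations; positional spread
uses 200 resampled standard deviations of 1000 points per axis. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
equal configurations reproduce byte-identical outputs.

## Numerical choices and degenerate inputs

* Circle fits drop points beyond 2.5 robust sigmas of radial residual, at
  most three passes, and never discard more than 60 % of a contour.
* Ray–sphere back-projection takes the nearest positive intersection;
  misses raise a per-frame flag.
* Gaze directions of zero length, coincident fish, zero-variance
  correlations, empty bootstrap strata, and out-of-arena trajectories all
  raise typed exceptions rather than returning sentinels.
* The pose smoother is a centered moving average (default window 5 frames
  at 90 fps) over positions, headings (renormalized), roll, bone angles
  and vertices — a deterministic, testable stand-in for a learned temporal
  smoother; angle averaging assumes small inter-frame changes and does not
  unwrap.
* Detected offsets are clamped to the geometric bound |o| ≤ 0.5 (fit noise
  can push a rim pupil marginally past it).

## Problem sizes

The shipped benchmarks use the study's published sizes where stated — 500
synthesized eye images at w = 120, 200 bootstrap iterations with
3000+3000-point batches — and a 200-frame, two-fish scene for the
end-to-end checks, which is enough for the sway/bob cycles to cover the
position-angle range several times over.

## Known limitations

* The sclera detector assumes one dominant bright disk per crop; crops
  containing two eyes or bright reflections need external masks.
* Torsional (cyclorotational) eye movement and pupil dilation are not
  modeled; the eye is a rigid sphere.
* The LBS inverse used nowhere at runtime is approximate for large bends;
  scenes store the rest mesh so reloading is exact.
* Real-video quantities that depend on the study's recordings (the
  published r = −0.69, the 45 499-frame counts, the −0.00195 slope) are
  reproduced only in sign and structure by the synthetic scenes, not in
  value.
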