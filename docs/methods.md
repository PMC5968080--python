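# Methods

This note records the models behind `disc3d`, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic-scanner tests do and do not establish about real data.

## Pose program

The gimbal orients the specimen so the (fixed) camera sees it from view
direction v(θ, φ) = (cos θ cos φ, cos θ sin φ, sin θ), with the support pin
along laboratory +Z. The program places tilt rings at every multiple of the
nominal spacing δ from −90° to +90°; the ring at tilt θ holds
round((360/δ)·cos θ) equally spaced rotations starting at φ = 0, and each
pole is a single pose. The cosine factor keeps the azimuthal arc length
constant, so the realized mean nearest-neighbour spacing tracks δ closely
(10.00° measured for δ = 10°, 412 poses).

Poses too close to the pin cannot be imaged: the pin, its adapter, and the
dome slot block the view. This is modelled as a symmetric double cone about
±Z with a configurable half-angle; 15° removes exactly the two polar poses
and the two 6-pose rings at tilt ±80°, i.e. 14 poses, leaving 398. The cone
is a geometric stand-in for the true hardware envelope — any exclusion set
with the same angular extent would behave identically downstream, since
excluded poses are simply skipped.

Ordering is by ring from the lower pole upward, then by ascending rotation,
so manifests are byte-reproducible.

## Rail geometry, the per-slice scale law, and its calibration

Focus is swept by advancing the whole camera along a macro rail in steps of
Δz while the lens focus distance z_f stays fixed. Consequences:

1. in-focus content is always imaged at the same magnification, but each
   slice has a different projection centre — a best-focus composite of raw
   slices is *not* a pinhole image;
2. the plane in focus at slice i sits (i − ref)·Δz farther from the
   *reference* slice's projection centre, so mapping slice i's in-focus
   content to the reference perspective requires an isotropic rescale about
   the principal point by the exact projective factor
   **s_i = 1/(1 + β(i − ref))**, β = Δz/z_f;
3. a *fixed* flat target photographed through the stack changes its
   projected scale by the exact *linear* law
   **spacing_ref/spacing_i = 1 − β(i − ref)**, because the camera-to-target
   distance shrinks linearly.

Points 2 and 3 involve the same single parameter β but different functional
forms (they agree to first order in β·Δi; for β = 0.03 over ±10 slices they
differ by ~1%, which matters at the stated 2% recovery tolerance).
`calibrate_from_target` therefore fits the linear measurement law (one-
dimensional least squares on the measured spacing ratios; residual RMS
stored as a quality figure), and `slice_scale` applies the projective law
with the fitted β. The projective form rather than its linear approximation
is used for compositing because the approximation error grows with stack
length and β.

Dot centroids are localized by a few mean-shift iterations of a Gaussian-
windowed darkness-weighted centroid (window ≈ 0.85 of the dot radius). A
plain thresholded centroid carries a pixel-grid truncation bias that is
correlated across a regular dot lattice and biased β by up to ~30% at small
β; the mean-shift refinement brings recovery to ≤ 0.3% relative for
β ∈ {0.002, 0.01, 0.03} on rendered targets.

The reference slice defaults to the middle of the stack, which halves the
maximum |β·Δi| and hence the worst-case interpolation loss of rescaling.

Object-side pixel size is pitch/magnification: 5.5 µm / 1.26 = 4.37 µm for
the default camera configuration (2048², 5.5 µm pitch).

## Synthetic scanner

The generator renders analytic solids — sphere, capsule, flat-capped
cylinder, torus, half-space — with exact ray intersections (the torus by
sphere-tracing its signed distance function inside its analytic bounding
sphere, ε = 10⁻⁴ mm). Per pose, the camera sits at z_f·(1 + margin) along
the view direction looking at the rotation centre, up = world +Z projected
off the view axis (+X at the poles), image rows growing downward; slice i
advances the camera (i − n/2)·Δz toward the scene. The same extrinsics
function drives projection in the visual-hull stage, so the renderer and
the carver can never disagree about conventions.

Front light is flat ambient shading of a procedurally textured albedo
(seeded trilinear value noise with configurable amplitude and correlation
length) on a uniform 0.8 background — diffuse-dome imaging genuinely looks
flat, with no shadows or highlights. Back light renders solids black on
white. Defocus uses the thin-lens circle of confusion c(z) = k·|z − z_f|/z
pixels with k = focal_px·A/z_f (A the aperture diameter, default 20 mm,
chosen so one rail step at the default Δz = 0.5 mm, z_f = 100 mm grows the
blur by about the acceptable CoC of ~2 px — i.e. the rail step is matched
to the depth of field, as a sensible acquisition would); pixels are binned
by depth into one-rail-step bins, each bin Gaussian-blurred (σ = c/2,
capped at c_max = 12 px) and composited far-to-near, which is occlusion-
correct for opaque scenes. Rendering is bit-identical for a fixed seed.

What the generator does **not** emulate: sensor noise and vignetting,
specular or translucent materials, soft shadows, motion or vibration
between slices, rail hysteresis, and partial-occlusion transparency at
defocused edges beyond the Gaussian model. Tests passing on this generator
demonstrate the algorithms' geometric and photometric correctness under the
stated model, not robustness to those real-world effects.

## EDOF compositing

Per stack: (1) rescale every slice to the reference perspective (bilinear,
edge fill); (2) sharpness = |Laplacian| of the σ = 1 px Gaussian-smoothed
gray image, box-summed over a 9 px window (separable, noise-robust, zero on
constant images); (3) winner-take-all over slices, ties broken toward the
camera-near slice (occlusion-correct for opaque specimens); (4) parabolic
sub-slice refinement of the winning index (±0.5 slice cap); (5) 5×5 median
filter of the index map to suppress salt-and-pepper depth outliers that
would otherwise cause halo artifacts; (6) colour = linear blend of the two
slices bracketing the smoothed fractional index, which removes slice-
quantization banding; (7) pixels whose best sharpness falls below a
threshold (Otsu on the confidence map, floored at 10⁻⁴ of its maximum) are
flagged background and filled from the reference slice — background is
replaced by masking downstream anyway.

The sharpness window, median size, blend rule and background rule are
package design choices; nothing in the underlying acquisition model forces
them. Measured behaviour at defaults on rendered phantoms: depth-index RMS
error 0.32 slices on a tilted textured plane spanning slices ~4–16 of 21
(99%+ of pixels within ±1 slice), and landmark positions within 0.25 px of
the analytic reference-pinhole projection on a two-dot two-depth scene
where uncalibrated compositing errs by ~2.9 px.

## Masking

Back-light EDOF images are thresholded globally (Otsu by default, fixed
value overridable), closed with a radius-2 disk, hole-filled, and cleaned
of components below 50 px. The silhouette becomes the alpha channel of the
front-light EDOF PNG (255 specimen / 0 background, RGB untouched, lossless
round-trip). The support pin is opaque and stays in the mask; removing it
is a modelling-stage concern. Measured IoU against rendered ground-truth
silhouettes is ≥ 0.98 per pose at defaults when the stack's focal sweep
covers the whole specimen — the same condition a real scan must satisfy.

## Visual hull

A voxel survives iff its centre projects inside the image frame and inside
the silhouette of *every* accessible view (centre-point projection, no
conservative footprint — adequate at ≥ 100³ voxels with ≥ 26 views; both
are configurable). The hull contains the object by construction, adding
views can only shrink it, and concavities never appear on silhouettes, so
hull volume strictly over-estimates e.g. a torus (measured +1.3% for a
2.5/0.8 mm torus under 26 views at 256 px masks — the waist depression
between tangent cones survives carving). Mask pixelation erodes the hull by
about half an object pixel per view, so mask resolution must be high enough
that this erosion stays below the concavity excess being measured.

Surfaces are extracted by marching cubes at level 0.5 after zero-padding
and 2× nearest-neighbour upsampling of the occupancy; the upsampling keeps
the isosurface near the voxel-cell boundary (an isolated voxel yields
~0.71 of its cell volume rather than the 1/6 octahedron of plain marching
cubes) and changes large-hull volumes by < 0.1%. Meshes are watertight and
outward-oriented. A rendered 3 mm sphere carved at 128³ from 26 EDOF-
derived masks reproduces the analytic volume to well within 6% end to end.

## Morphometry and reliability

Area sums triangle areas; volume is the absolute signed sum of origin
tetrahedra (divergence theorem), reported in cm²/cm³ for mm meshes; volume
requires watertightness and reports the offending boundary-edge count
otherwise. Both are rigid-motion invariant and scale as k² / k³ exactly.

Reliability of replicate measurements uses the sample SD (n−1): CV% =
100·SD/mean, maximum relative deviation = 100·max|x − mean|/mean (from the
range endpoints when only summaries are available), and a two-sided
variance-ratio F test (larger variance over smaller; p = 2·tail, capped at
1). Rounding happens only at report time: 1 d.p. for percentages, 2 d.p.
for mm. The bundled 22-observer beetle summary table (scutellum width and
hind-tibia length, 2D microscope vs 3D model) reproduces CVs of 8.0%, 8.3%
and 1.1% and maximum deviations of 5.5% and 2.4% from its printed
means/SDs/ranges. Note the printed SDs are themselves rounded: F statistics
recomputed from them (e.g. (0.21/0.07)² = 9.0) differ from values computed
on raw replicate data, so the F test is checked against its significance
bound (p < 10⁻⁴ at n = 22 per group for F ≈ 10), not against an exact F. A
generic Friedman test is deliberately not bundled: the raw 22×2 replicate
matrix is not available, so nothing could validate it.

## Problem sizes used by the test suite

The suite exercises every stage at desk scale: 160–256 px images, 5–21
slice stacks, 26-view hulls at 96–128³ voxels, chosen so the full suite
runs in well under a minute of rendering plus a few seconds of carving.
All tolerances above were measured at those sizes; the algorithms contain
nothing resolution-specific beyond the discretization effects already
discussed.

## Known limitations

- The pin-exclusion cone is a count-matched stand-in for the true hardware
  envelope, not a CAD-derived one.
- The defocus model is an isotropic Gaussian per depth bin; real bokeh is
  aperture-shaped and asymmetric near occlusion boundaries.
- The hull stage replaces a structure-from-motion + meshing pipeline; it
  shares the SfS inability to recover indentations and needs the camera
  model to be exact, which the synthetic scanner guarantees but a real rig
  only approximates after calibration.
- `compose_edof` holds all rescaled slices in memory (n·H·W·3 doubles);
  fine at scanner resolutions, but a 4 MP × 400-slice stack would want a
  streaming implementation.
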