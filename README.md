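# disc3d

Software pipeline of an automated all-sphere digitization scanner for pinned
insects and other small specimens: spherical **pose programs** for a two-axis
gimbal, **calibrated extended-depth-of-field (EDOF)** compositing of focus
stacks that stays consistent with a single pinhole perspective, **back-light
silhouette masking**, **visual-hull** 3D reconstruction from the masked
views, and **mesh morphometry** (surface area, volume, measurement
reliability). A built-in synthetic scanner renders every input the hardware
would produce, with analytic ground truth, so the whole chain runs and is
tested without any device.

## Who this is for

Collections digitization and functional-morphology groups that image pinned
specimens with focus-stacking multi-view rigs, and anyone who needs a
desk-scale, fully reproducible stand-in for such a rig to develop or validate
processing stages.

## The core ideas

**Pose program.** Views cover the sphere at a nominal neighbour spacing δ:
tilt rings every δ from −90° to +90°, the ring at tilt θ holding
round((360/δ)·cos θ) equally spaced rotations, each pole once. For δ = 10°
this gives 412 poses; a symmetric double cone of half-angle 15° about the
support-pin axis removes the 14 poses the pin hardware blocks, leaving 398.

**Calibrated EDOF.** A focus stack is captured by advancing the camera along
a macro rail with the lens focus fixed at z_f, so each slice has its own
projection centre and a naive best-focus composite is not a pinhole image.
The in-focus content of slice *i* maps to the reference slice's perspective
by an isotropic rescale about the principal point,

    s_i = 1 / (1 + β (i − ref)),      β = Δz / z_f,

because that content sits (i − ref)·Δz farther from the reference projection
centre. β is measured once per optical configuration from a stack of a fixed
flat dot grid, whose projected spacing obeys the exact linear law
spacing_ref/spacing_i = 1 − β(i − ref). After rescaling, standard
depth-from-focus machinery (smoothed-Laplacian sharpness, winner-take-all
with parabolic sub-slice refinement, median smoothing, bracketing-slice
blend) produces the composite plus a fractional depth-index map.

**Silhouettes and the visual hull.** Back-light images show the specimen
dark on a white dome; a global threshold plus light morphology yields the
silhouette, which is stored in the alpha channel of the front-light EDOF
PNG. The visual hull — the intersection of all silhouette cones — is carved
on a voxel grid and meshed by marching cubes; it contains the true object,
so its volume is an upper bound (concavities are unrecoverable by
construction).

**Morphometry.** Surface area (summed triangle areas, cm²) and volume
(divergence theorem, cm³) of watertight meshes; replicate-measurement
reliability via the coefficient of variation CV = 100·SD/mean, the maximum
relative deviation from the mean, and a two-sided variance-ratio F test.

## Worked example

Pose accounting for the standard program:

```
$ disc3d poses --spacing 10 --cone 15
poses: 412
accessible: 398
excluded: 14
mean nearest-neighbour spacing: 10.00 deg
```

412 views at a realized mean neighbour spacing of 10.00°, of which 14 lie
within 15° of the pin axis and cannot be imaged.

A complete synthetic scan → EDOF → mask → hull → measure run (6-pose
program, 96 px images, 7-slice stacks; `demo.yaml` holds exactly the keys
shown under Configuration below):

```
$ disc3d run --config demo.yaml
pipeline artifacts in scratch/readme_scan
$ disc3d measure --mesh scratch/readme_scan/hull.obj
surface area: 1.733 cm^2
volume: 0.1404 cm^3
```

The demo scene is a 3 mm textured sphere on a 0.25 mm support pin; with only
4 accessible equatorial views the hull overestimates the true solid
(≈ 0.114 cm³), exactly as shape-from-silhouette must — more views tighten
the bound (26 views recover the sphere volume to within a few percent; see
the test suite).

```
$ cat scratch/readme_scan/report.csv
quantity,value,units
n_poses,6,poses
n_accessible,4,poses
hull_voxels,33224,voxels
surface_area,1.73323,cm^2
volume,0.140448,cm^3
```

## Configuration

One YAML file drives the `run` pipeline; unknown keys are rejected by name.

```yaml
scan_id: demo
seed: 1
out_dir: scratch/readme_scan
poses: {spacing_deg: 90, cone_deg: 15}
camera: {width_px: 96, fit_scene: true}
stack: {n_slices: 7, step_um: 2200}
scene: {preset: demo}
hull: {resolution: 96}
```

Subcommands: `poses`, `simulate`, `calibrate`, `edof`, `mask`, `hull` (via
`run`), `measure`, `reliability`, `run`. Re-running `run` skips poses already
recorded as done in `manifest.json`, and two runs with the same config and
seed produce bit-identical PNGs.

## Layout

- `src/disc3d/poses.py` — pose programs, spacing statistics, pin exclusion
- `src/disc3d/optics.py` — pinhole arithmetic, per-slice scale law, target calibration
- `src/disc3d/synth.py` — the synthetic scanner (analytic solids, thin-lens defocus, scan writer)
- `src/disc3d/edof.py` — calibrated EDOF compositing and depth-index maps
- `src/disc3d/mask.py` — back-light segmentation and alpha masking
- `src/disc3d/hull.py` — voxel carving and marching-cubes surface extraction
- `src/disc3d/morpho.py` — mesh area/volume and reliability statistics
- `src/disc3d/{config,pipeline,cli}.py` — YAML config, orchestration, CLI

`docs/methods.md` describes the models, parameter choices, and limitations.
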