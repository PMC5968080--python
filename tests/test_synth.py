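"""The synthetic scanner against its own analytic ground truth."""

import math

import numpy as np
import pytest

from disc3d.errors import InvalidInputError, InvalidParameterError
from disc3d.optics import calibrate_from_target, detect_grid_spacing, slice_scale
from disc3d.poses import Pose, PoseProgram, apply_exclusion, generate_pose_program
from disc3d.synth import (
    Capsule,
    Cylinder,
    FocusStack,
    Scene,
    Sphere,
    StackConfig,
    Torus,
    camera_for_scene,
    make_scan,
    project_points,
    render_pose_stack,
    render_target_stack,
    render_view,
)


@pytest.fixture(scope="module")
def cam():
    return camera_for_scene(3.0, width_px=160)


def test_backlight_silhouette_radius(sphere_scene, sphere_camera):
    """Projected sphere silhouette radius matches the pinhole prediction."""
    pose = Pose.from_angles(0, 30, 120)
    _, _, hit = render_view(sphere_scene, pose, sphere_camera, "back")
    r_px = math.sqrt(hit.sum() / math.pi)
    d = sphere_camera.focus_distance_mm
    r_pred = sphere_camera.focal_px * 3.0 / math.sqrt(d * d - 9.0)
    assert abs(r_px - r_pred) < 1.0
    # and within a pixel of the small-angle r * magnification / pitch value
    r_simple = 3.0 * sphere_camera.magnification * 1000 / sphere_camera.pixel_pitch_um
    assert abs(r_px - r_simple) < 1.0


def test_ground_truth_depth_at_center(sphere_scene, sphere_camera):
    pose = Pose.from_angles(0, -45, 200)
    _, depth, hit = render_view(sphere_scene, pose, sphere_camera, "front")
    ppx, ppy = sphere_camera.principal_point_px
    z = depth[int(round(ppy)), int(round(ppx))]
    expect = sphere_camera.focus_distance_mm - 3.0
    assert z == pytest.approx(expect, rel=5e-3)


def test_single_slice_no_defocus_equals_pinhole_render(sphere_scene, cam):
    pose = Pose.from_angles(0, 10, 45)
    stack, _, _ = render_pose_stack(
        sphere_scene, pose, cam, 1, 500, "front", seed=4, aperture_mm=0.0
    )
    sharp, _, _ = render_view(sphere_scene, pose, cam, "front", seed=4)
    assert np.array_equal(stack.slices[0], np.clip(sharp, 0, 1))


def test_silhouette_equals_thresholded_backlight_at_zero_defocus(sphere_scene, cam):
    pose = Pose.from_angles(0, 60, 10)
    stack, _, gt_sil = render_pose_stack(
        sphere_scene, pose, cam, 1, 500, "back", seed=0, aperture_mm=0.0
    )
    assert np.array_equal(stack.slices[0].mean(axis=2) < 0.5, gt_sil)


def test_rendering_deterministic(beetle_scene, cam):
    pose = Pose.from_angles(0, 25, 80)
    a, da, sa = render_pose_stack(beetle_scene, pose, cam, 3, 1000, "front", seed=9)
    b, db, sb = render_pose_stack(beetle_scene, pose, cam, 3, 1000, "front", seed=9)
    for x, y in zip(a.slices, b.slices):
        assert np.array_equal(x, y)
    assert np.array_equal(np.nan_to_num(da, posinf=0), np.nan_to_num(db, posinf=0))
    assert np.array_equal(sa, sb)
    c, _, _ = render_pose_stack(beetle_scene, pose, cam, 3, 1000, "front", seed=10)
    assert any(not np.array_equal(x, y) for x, y in zip(a.slices, c.slices))


def test_grid_spacing_follows_projective_scale_law(cam):
    """Dot spacing across slices tracks the slice-scale law (small beta)."""
    beta = 0.002
    stack = render_target_stack(cam, 21, beta * 1e5, grid_pitch_mm=0.8)
    cal = calibrate_from_target(stack)
    sp_ref = detect_grid_spacing(stack.slices[10])
    for i in (0, 5, 15, 20):
        rendered = detect_grid_spacing(stack.slices[i])
        predicted = sp_ref / slice_scale(i, cal)
        assert predicted == pytest.approx(rendered, rel=2e-3)


def test_primitive_intersection_consistency():
    """Ray hits agree with membership tests for capsule/cylinder/torus."""
    solids = [
        Capsule(p0=(0, 0, -2), p1=(0, 0, 2), radius=0.7),
        Cylinder(p0=(0, 0, -2), p1=(0, 0, 2), radius=0.7),
        Torus(center=(0, 0, 0), axis=(0, 0, 1), major_radius=1.6, minor_radius=0.5),
    ]
    rng = np.random.default_rng(0)
    origins = rng.normal(size=(200, 3)) * 0.3 + np.array([8.0, 0.0, 0.0])
    targets = rng.normal(size=(200, 3)) * 1.2
    dirs = targets - origins
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    for solid in solids:
        t = solid.intersect(origins, dirs)
        hits = np.isfinite(t)
        pts = origins[hits] + t[hits, None] * dirs[hits]
        # the ray enters the solid just past the hit point (non-grazing rays)
        just_inside = pts + 5e-3 * dirs[hits]
        just_outside = pts - 5e-3 * dirs[hits]
        assert solid.contains(just_inside).mean() > 0.95
        assert (~solid.contains(just_outside)).mean() > 0.95
        # rays aimed at an interior point must hit
        interior = solid.contains(targets)
        assert hits[interior].all()


def test_project_points_matches_silhouette(sphere_scene, sphere_camera):
    """The shared projection maps the sphere edge onto the silhouette edge."""
    pose = Pose.from_angles(0, 45, 30)
    _, _, hit = render_view(sphere_scene, pose, sphere_camera, "back")
    uv, depth = project_points(np.zeros((1, 3)), pose, sphere_camera)
    assert depth[0] == pytest.approx(sphere_camera.focus_distance_mm, rel=1e-12)
    c, r = uv[0]
    assert hit[int(round(r)), int(round(c))]


def test_empty_scene_rejected():
    with pytest.raises(InvalidInputError):
        Scene(solids=())


def test_stack_invariants():
    img = np.zeros((8, 8, 3))
    with pytest.raises(InvalidInputError):
        FocusStack(slices=[img, img], rail_positions_mm=np.array([1.0, 0.5]))
    with pytest.raises(InvalidInputError):
        FocusStack(slices=[img, np.zeros((4, 4, 3))],
                   rail_positions_mm=np.array([0.0, 1.0]))
    with pytest.raises(InvalidInputError):
        FocusStack(slices=[], rail_positions_mm=np.array([]))


def test_make_scan_bookkeeping(tmp_path, beetle_scene):
    """6-pose program, 5 slices: one stack pair per accessible pose."""
    import tifffile

    cam = camera_for_scene(6.75, width_px=48)
    prog = generate_pose_program(90)
    cfg = StackConfig(n_slices=5, step_um=3000)
    out = make_scan(beetle_scene, prog, cam, cfg, tmp_path / "scan", seed=0)
    pose_dirs = sorted(p for p in out.iterdir() if p.is_dir())
    assert len(pose_dirs) == 6
    stack = tifffile.imread(pose_dirs[0] / "front.tif")
    assert stack.shape[0] == 5
    manifest = (out / "manifest.csv").read_text().strip().splitlines()
    assert len(manifest) == 7  # header + 6 poses


def test_make_scan_standard_program_writes_398_pose_dirs(tmp_path, beetle_scene):
    """The 10 deg program with the 15 deg pin exclusion scans 398 poses."""
    cam = camera_for_scene(6.75, width_px=24)
    prog = apply_exclusion(generate_pose_program(10), 15.0)
    out = make_scan(beetle_scene, prog, cam,
                    StackConfig(n_slices=1, step_um=3000, back_n_slices=1),
                    tmp_path / "scan", seed=0)
    assert len([p for p in out.iterdir() if p.is_dir()]) == 398
    manifest = (out / "manifest.csv").read_text().strip().splitlines()
    assert len(manifest) == 399


def test_make_scan_skips_inaccessible(tmp_path, beetle_scene):
    cam = camera_for_scene(6.75, width_px=32)
    prog = apply_exclusion(generate_pose_program(90), 15.0)
    assert prog.n_accessible == 4
    out = make_scan(beetle_scene, prog, cam,
                    StackConfig(n_slices=1, step_um=3000), tmp_path / "scan", seed=0)
    assert len([p for p in out.iterdir() if p.is_dir()]) == 4
    none = PoseProgram(90.0, tuple(), exclusion_cone_deg=0.0)
    with pytest.raises(InvalidInputError):
        make_scan(beetle_scene, none, cam, StackConfig(), tmp_path / "scan2")
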