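"""Shared fixtures: small synthetic scenes rendered once per session.

All imagery is generated by :mod:`disc3d.synth` at test time; the heavier
renders (focus stacks, multi-view mask sets) are session-scoped so the
stage tests and the acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from disc3d.edof import compose_edof
from disc3d.mask import segment_backlight
from disc3d.optics import StackCalibration
from disc3d.poses import Pose, PoseProgram
from disc3d.synth import (
    Capsule,
    HalfSpace,
    Scene,
    Sphere,
    camera_for_scene,
    render_pose_stack,
    render_view,
)

SPHERE_RADIUS_MM = 3.0


@pytest.fixture(scope="session")
def sphere_scene() -> Scene:
    return Scene(solids=(Sphere(center=(0, 0, 0), radius=SPHERE_RADIUS_MM),))


@pytest.fixture(scope="session")
def sphere_camera():
    return camera_for_scene(SPHERE_RADIUS_MM, width_px=256)


@pytest.fixture(scope="session")
def beetle_scene() -> Scene:
    """Textured sphere on a support pin, all within focal-sweep reach."""
    return Scene(
        solids=(
            Sphere(center=(0, 0, 0), radius=3.0, albedo=(0.45, 0.32, 0.18),
                   texture_amp=0.4, texture_scale_mm=0.25),
            Capsule(p0=(0, 0, -6.5), p1=(0, 0, -2.0), radius=0.25,
                    albedo=(0.55, 0.55, 0.58), texture_amp=0.1),
        )
    )


@pytest.fixture(scope="session")
def ring_program_26() -> PoseProgram:
    """26 views: three tilt rings of 8 plus the two poles."""
    angles = [(t, k * 45.0) for t in (-45, 0, 45) for k in range(8)]
    angles += [(90, 0.0), (-90, 0.0)]
    return PoseProgram.from_angles(angles)


@pytest.fixture(scope="session")
def sphere_gt_masks(sphere_scene, sphere_camera, ring_program_26):
    """Analytic (ray-cast) silhouettes of the sphere for all 26 views."""
    masks = {}
    for pose in ring_program_26.poses:
        _, _, hit = render_view(sphere_scene, pose, sphere_camera, "back")
        masks[pose.index] = hit
    return masks


@pytest.fixture(scope="session")
def tilted_plane_bundle():
    """Textured 45-ish deg plane phantom: stack + calibration + GT indices.

    The plane's depth range spans slices ~4 to ~16 of a 21-slice stack, so
    every visible pixel has in-focus support away from the stack ends.
    """
    cam = camera_for_scene(3.0, width_px=160)
    n, step = 21, 500.0
    plane = HalfSpace(point=(0, 0, 0), normal=(1, 0, 0.8), texture_amp=0.45,
                      texture_scale_mm=0.25, albedo=(0.5, 0.45, 0.4))
    scene = Scene(solids=(plane,))
    pose = Pose.from_angles(0, 0, 0)
    stack, gt_depth, _ = render_pose_stack(scene, pose, cam, n, step, "front", seed=3)
    cal = StackCalibration.from_geometry(n, step, cam.focus_distance_mm)
    gt_index = n // 2 + (gt_depth - cam.focus_distance_mm) / (step * 1e-3)
    return {"stack": stack, "cal": cal, "gt_index": gt_index, "camera": cam}


@pytest.fixture(scope="session")
def two_dot_bundle():
    """Two textured dot-spheres in focus near the two stack ends.

    Both sit on the same side of the principal point, so a perspective
    error does not cancel in their separation.
    """
    cam = camera_for_scene(5.0, width_px=192)
    n, step = 21, 500.0
    ref = n // 2
    dz = step * 1e-3
    dot_a = Sphere(center=(-(2 - ref) * dz, 1.5, 0.0), radius=0.35,
                   albedo=(0.1, 0.1, 0.1), texture_amp=0.6, texture_scale_mm=0.12)
    dot_b = Sphere(center=(-(18 - ref) * dz, 4.2, 0.0), radius=0.35,
                   albedo=(0.1, 0.1, 0.1), texture_amp=0.6, texture_scale_mm=0.12)
    scene = Scene(solids=(dot_a, dot_b))
    pose = Pose.from_angles(0, 0, 0)
    stack, _, _ = render_pose_stack(scene, pose, cam, n, step, "front", seed=5)
    cal = StackCalibration.from_geometry(n, step, cam.focus_distance_mm)
    return {
        "stack": stack, "cal": cal, "camera": cam, "pose": pose,
        "centers": np.array([dot_a.center, dot_b.center]),
    }


@pytest.fixture(scope="session")
def sphere_scan_hull(sphere_scene, ring_program_26):
    """Full pipeline on the sphere: back-light stacks → EDOF → masks → hull."""
    from disc3d.hull import carve, extract_surface

    cam = camera_for_scene(SPHERE_RADIUS_MM, width_px=160)
    n, step = 5, 1500.0
    cal = StackCalibration.from_geometry(n, step, cam.focus_distance_mm)
    masks = {}
    for pose in ring_program_26.poses:
        back, _, _ = render_pose_stack(
            sphere_scene, pose, cam, n, step, "back", seed=11 + pose.index
        )
        sil = segment_backlight(compose_edof(back, cal).image)
        masks[pose.index] = sil
    grid = carve(masks, list(ring_program_26.poses), cam,
                 half_extent_mm=1.2 * SPHERE_RADIUS_MM, resolution=128)
    mesh = extract_surface(grid)
    return {"grid": grid, "mesh": mesh, "camera": cam, "masks": masks}
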