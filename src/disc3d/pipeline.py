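"""The automated scan → EDOF → mask → hull → measure pipeline.

Runs every stage for all accessible poses of the configured program,
entirely on the synthetic scanner, and leaves a scan directory containing
per-pose masked EDOF PNGs, a machine-readable ``manifest.json``, the
carved hull as ``hull.obj`` and a morphometry ``report.csv``.  Completed
poses (recorded in the manifest) are skipped on re-runs, so an
interrupted scan resumes where it stopped.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import edof as edof_mod
from . import hull as hull_mod
from . import mask as mask_mod
from . import morpho
from .config import PipelineConfig
from .optics import calibrate_from_target
from .poses import apply_exclusion, generate_pose_program, write_pose_csv
from .synth import render_pose_stack, render_target_stack

log = logging.getLogger("disc3d")

__all__ = ["run_pipeline"]


def _load_manifest(path: Path) -> dict:
    if path.exists():
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    return {"poses": {}, "stages": {}}


def _save_manifest(path: Path, manifest: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline described by ``cfg``; returns the scan dir."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = _load_manifest(manifest_path)
    manifest["scan_id"] = cfg.scan_id
    manifest["seed"] = cfg.seed

    scene = cfg.build_scene()
    camera = cfg.build_camera(scene)
    stack_cfg = cfg.build_stack_config()

    program = generate_pose_program(float(cfg.poses.get("spacing_deg", 90.0)))
    program = apply_exclusion(program, float(cfg.poses.get("cone_deg", 15.0)))
    write_pose_csv(program, out / "poses.csv")
    log.info(
        "pose program: %d poses, %d accessible", len(program), program.n_accessible
    )

    # stack calibration from a rendered dot-grid target (once per scan)
    t = time.time()
    target = render_target_stack(camera, stack_cfg.n_slices, stack_cfg.step_um)
    cal = calibrate_from_target(target)
    cal.to_yaml(out / "calibration.yaml")
    log.info("calibration: beta=%.5f rms=%.2e (%.2fs)", cal.beta, cal.residual_rms,
             time.time() - t)

    edof_params = edof_mod.EdofParams(
        window_px=int(cfg.edof.get("window_px", 9)),
        median_px=int(cfg.edof.get("median_px", 5)),
        confidence_floor=float(cfg.edof.get("confidence_floor", 1e-4)),
    )
    mask_params = mask_mod.MaskParams(
        threshold=cfg.mask.get("threshold"),
        closing_radius_px=int(cfg.mask.get("closing_radius_px", 2)),
        min_area_px=int(cfg.mask.get("min_area_px", 50)),
    )

    masks: dict[int, mask_mod.SilhouetteMask] = {}
    accessible = program.accessible_poses
    for pose in accessible:
        rec = manifest["poses"].get(str(pose.index), {})
        png = out / f"pose_{pose.index:04d}_masked.png"
        if rec.get("status") == "done" and png.exists():
            rgba = iio.imread(png)
            masks[pose.index] = mask_mod.SilhouetteMask.from_array(rgba[..., 3] > 0)
            log.info("pose %d: already done, skipped", pose.index)
            continue
        t = time.time()
        front, _, _ = render_pose_stack(
            scene, pose, camera, stack_cfg.n_slices, stack_cfg.step_um, "front",
            seed=cfg.seed + pose.index, aperture_mm=stack_cfg.aperture_mm,
            coc_max_px=stack_cfg.coc_max_px, margin=stack_cfg.margin,
        )
        back_n = stack_cfg.back_n_slices or stack_cfg.n_slices
        back, _, _ = render_pose_stack(
            scene, pose, camera, back_n, stack_cfg.step_um, "back",
            seed=cfg.seed + pose.index, aperture_mm=stack_cfg.aperture_mm,
            coc_max_px=stack_cfg.coc_max_px, margin=stack_cfg.margin,
        )
        front_edof = edof_mod.compose_edof(front, cal, edof_params, pose_index=pose.index)
        back_cal = cal if back_n == cal.n_slices else calibrate_from_target(
            render_target_stack(camera, back_n, stack_cfg.step_um)
        )
        back_edof = edof_mod.compose_edof(back, back_cal, edof_params, pose_index=pose.index)
        sil = mask_mod.segment_backlight(back_edof.image, mask_params)
        rgba = mask_mod.apply_alpha(front_edof.image, sil)
        iio.imwrite(png, rgba)
        masks[pose.index] = sil
        manifest["poses"][str(pose.index)] = {
            "status": "done",
            "tilt_deg": pose.tilt_deg,
            "rot_deg": pose.rot_deg,
            "masked_png": png.name,
            "seconds": round(time.time() - t, 3),
        }
        _save_manifest(manifest_path, manifest)
        log.info("pose %d: EDOF+mask in %.2fs", pose.index, time.time() - t)

    hull_obj = out / "hull.obj"
    report_csv = out / "report.csv"
    if manifest["stages"].get("hull") == "done" and hull_obj.exists() and report_csv.exists():
        log.info("hull + measure: already done, skipped")
    else:
        t = time.time()
        half_extent = float(
            cfg.hull.get("half_extent_mm", 1.15 * scene.bounding_radius())
        )
        grid = hull_mod.carve(
            masks, list(accessible), camera,
            half_extent_mm=half_extent,
            resolution=int(cfg.hull.get("resolution", 96)),
            margin=stack_cfg.margin,
        )
        mesh = hull_mod.extract_surface(grid)
        mesh.export(hull_obj)
        area = morpho.mesh_surface_area(mesh)
        vol = morpho.mesh_volume(mesh)
        with open(report_csv, "w", encoding="utf-8") as fh:
            fh.write("quantity,value,units\n")
            fh.write(f"n_poses,{len(program)},poses\n")
            fh.write(f"n_accessible,{program.n_accessible},poses\n")
            fh.write(f"hull_voxels,{grid.n_occupied},voxels\n")
            fh.write(f"surface_area,{area:.6g},cm^2\n")
            fh.write(f"volume,{vol:.6g},cm^3\n")
        manifest["stages"]["hull"] = "done"
        manifest["stages"]["measure"] = "done"
        _save_manifest(manifest_path, manifest)
        log.info("hull: %d voxels -> %.4g cm^3 in %.2fs", grid.n_occupied, vol,
                 time.time() - t)
    log.info("pipeline finished in %.2fs", time.time() - t0)
    return out
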