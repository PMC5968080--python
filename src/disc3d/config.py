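"""YAML pipeline configuration with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .optics import CameraModel
from .synth import Scene, Sphere, Capsule, StackConfig, camera_for_scene, demo_scene

__all__ = ["PipelineConfig", "load_config"]

_SECTIONS = {
    "scan_id": str,
    "seed": int,
    "out_dir": str,
    "poses": dict,
    "camera": dict,
    "stack": dict,
    "scene": dict,
    "edof": dict,
    "mask": dict,
    "hull": dict,
}

_KEYS = {
    "poses": {"spacing_deg", "cone_deg"},
    "camera": {
        "width_px", "height_px", "pixel_pitch_um", "magnification",
        "focus_distance_mm", "fit_scene", "fill",
    },
    "stack": {"n_slices", "step_um", "aperture_mm", "coc_max_px", "back_n_slices", "margin"},
    "scene": {"preset", "radius_mm", "pin"},
    "edof": {"window_px", "median_px", "confidence_floor"},
    "mask": {"threshold", "closing_radius_px", "min_area_px"},
    "hull": {"resolution", "half_extent_mm"},
}


def _check_keys(section: str, d: dict) -> dict:
    allowed = _KEYS[section]
    for k in d:
        if k not in allowed:
            raise ConfigError(f"unknown key {section}.{k!r} in config")
    return d


@dataclass
class PipelineConfig:
    scan_id: str = "scan"
    seed: int = 0
    out_dir: str = "scan_out"
    poses: dict = field(default_factory=lambda: {"spacing_deg": 90.0, "cone_deg": 15.0})
    camera: dict = field(default_factory=dict)
    stack: dict = field(default_factory=dict)
    scene: dict = field(default_factory=lambda: {"preset": "demo"})
    edof: dict = field(default_factory=dict)
    mask: dict = field(default_factory=dict)
    hull: dict = field(default_factory=dict)

    def build_scene(self) -> Scene:
        preset = self.scene.get("preset", "demo")
        radius = float(self.scene.get("radius_mm", 3.0))
        if preset == "demo":
            return demo_scene(self.seed)
        if preset == "sphere":
            solids = [Sphere(center=(0, 0, 0), radius=radius)]
            if self.scene.get("pin", False):
                solids.append(
                    Capsule(p0=(0, 0, -3 * radius), p1=(0, 0, -0.6 * radius), radius=0.08 * radius)
                )
            return Scene(solids=tuple(solids))
        raise ConfigError(f"unknown key scene.preset value {preset!r}")

    def build_camera(self, scene: Scene) -> CameraModel:
        c = dict(self.camera)
        if c.pop("fit_scene", True):
            return camera_for_scene(
                scene.bounding_radius(),
                width_px=int(c.get("width_px", 128)),
                height_px=int(c.get("height_px", c.get("width_px", 128))),
                focus_distance_mm=float(c.get("focus_distance_mm", 100.0)),
                fill=float(c.get("fill", 0.7)),
                pixel_pitch_um=float(c.get("pixel_pitch_um", 5.5)),
            )
        return CameraModel(
            pixel_pitch_um=float(c.get("pixel_pitch_um", 5.5)),
            width_px=int(c.get("width_px", 2048)),
            height_px=int(c.get("height_px", 2048)),
            magnification=float(c.get("magnification", 1.26)),
            focus_distance_mm=float(c.get("focus_distance_mm", 100.0)),
        )

    def build_stack_config(self) -> StackConfig:
        s = self.stack
        return StackConfig(
            n_slices=int(s.get("n_slices", 9)),
            step_um=float(s.get("step_um", 500.0)),
            aperture_mm=float(s.get("aperture_mm", 8.0)),
            coc_max_px=float(s.get("coc_max_px", 12.0)),
            margin=float(s.get("margin", 0.0)),
            back_n_slices=s.get("back_n_slices"),
        )


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline config; unknown keys are rejected by name."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key not in _SECTIONS:
            raise ConfigError(f"unknown key {key!r} in config")
        if not isinstance(val, _SECTIONS[key]) and not (
            _SECTIONS[key] is int and isinstance(val, int)
        ):
            raise ConfigError(f"config key {key!r} has wrong type")
        if key in _KEYS:
            _check_keys(key, val)
        setattr(cfg, key, val)
    return cfg
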