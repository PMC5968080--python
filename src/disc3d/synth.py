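"""Synthetic scanner: renders everything the hardware would capture.

The scanner images analytic solids (sphere, capsule, cylinder pin, torus,
half-space plane) with a thin-lens camera stepping along a macro rail.
Front lighting is flat ambient shading of a procedurally textured albedo
(the diffuse dome gives real scans the same flat look); back lighting
renders the solids black on a white background, producing silhouettes.
Defocus is modelled as a depth-dependent Gaussian blur whose
circle-of-confusion diameter is ``c(z) = k * |z - z_f| / z`` pixels, with
``k = focal_px * aperture_mm / z_f``; depth bins one rail step wide are
blurred separately and composited nearest-last, which is occlusion-correct
for opaque solids.

Everything is deterministic for a fixed seed, and every rendered quantity
has an analytic ground truth (projection, silhouette, depth), which is what
makes the module usable as the oracle for the processing stages.

Geometry conventions (shared with the visual-hull stage):

* the scene's rotation centre is the world origin unless stated otherwise;
* a pose's ``view_dir`` points from the rotation centre toward the camera;
* the *reference* camera centre sits at ``z_f * (1 + margin)`` along
  ``view_dir``; slice ``i`` advances the camera by ``(i - ref) * step``
  toward the scene, keeping the lens focus fixed at ``z_f``, so the plane
  in focus sweeps from the near side to the far side of the specimen;
* the camera up vector is world +Z projected perpendicular to the view
  (world +X at the poles); image rows grow downward.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError
from .optics import CameraModel
from .poses import Pose, PoseProgram

__all__ = [
    "Sphere",
    "Capsule",
    "Cylinder",
    "Torus",
    "HalfSpace",
    "Scene",
    "FocusStack",
    "StackConfig",
    "camera_for_scene",
    "camera_frame",
    "camera_center",
    "project_points",
    "render_view",
    "render_ground_truth",
    "render_pose_stack",
    "render_target_stack",
    "make_scan",
]

_BG_FRONT = 0.8  # diffuse dome interior seen behind the specimen


# ---------------------------------------------------------------------------
# analytic primitives


@dataclass(frozen=True)
class _Solid:
    albedo: tuple[float, float, float] = (0.5, 0.4, 0.3)
    texture_amp: float = 0.35
    texture_scale_mm: float = 0.15

    def intersect(self, o, d):  # pragma: no cover - abstract
        raise NotImplementedError

    def contains(self, p):  # pragma: no cover - abstract
        raise NotImplementedError

    def bounding_radius(self, about) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


def _first_positive(*ts):
    """Element-wise smallest positive candidate among ray parameters."""
    out = np.full(ts[0].shape, np.inf)
    for t in ts:
        out = np.where((t > 1e-9) & (t < out), t, out)
    return out


@dataclass(frozen=True)
class Sphere(_Solid):
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 1.0

    def intersect(self, o, d):
        oc = o - np.asarray(self.center)
        b = np.einsum("...i,...i->...", d, oc)
        c = np.einsum("...i,...i->...", oc, oc) - self.radius**2
        disc = b * b - c
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1 = np.where(ok, -b - sq, np.inf)
        t2 = np.where(ok, -b + sq, np.inf)
        return _first_positive(t1, t2)

    def contains(self, p):
        return ((p - np.asarray(self.center)) ** 2).sum(-1) <= self.radius**2

    def bounding_radius(self, about):
        return float(np.linalg.norm(np.asarray(self.center) - about) + self.radius)

    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class _Tube(_Solid):
    """Shared quadric machinery for capsule and cylinder (axis p0->p1)."""

    p0: tuple[float, float, float] = (0.0, 0.0, -1.0)
    p1: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float = 0.3

    @property
    def _axis(self):
        a = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        L = np.linalg.norm(a)
        return a / L, L

    def _side_hits(self, o, d):
        """Ray parameters of infinite-cylinder side hits + axial params."""
        w, L = self._axis
        oc = o - np.asarray(self.p0, float)
        d_perp = d - np.einsum("...i,i->...", d, w)[..., None] * w
        o_perp = oc - np.einsum("...i,i->...", oc, w)[..., None] * w
        a = np.einsum("...i,...i->...", d_perp, d_perp)
        b = np.einsum("...i,...i->...", d_perp, o_perp)
        c = np.einsum("...i,...i->...", o_perp, o_perp) - self.radius**2
        disc = b * b - a * c
        ok = (disc >= 0) & (a > 1e-12)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(ok, (-b - sq) / a, np.inf)
            t2 = np.where(ok, (-b + sq) / a, np.inf)
        dw = np.einsum("...i,i->...", d, w)
        ow = np.einsum("...i,i->...", oc, w)
        return (t1, t2), dw, ow, L

    def bounding_radius(self, about):
        r0 = np.linalg.norm(np.asarray(self.p0, float) - about) + self.radius
        r1 = np.linalg.norm(np.asarray(self.p1, float) - about) + self.radius
        return float(max(r0, r1))


@dataclass(frozen=True)
class Capsule(_Tube):
    """Cylinder with hemispherical caps; the support pin is a thin one."""

    def intersect(self, o, d):
        (t1, t2), dw, ow, L = self._side_hits(o, d)
        cands = []
        for t in (t1, t2):
            h = ow + t * dw
            cands.append(np.where((h >= 0) & (h <= L), t, np.inf))
        for cap in (self.p0, self.p1):
            s = Sphere(center=tuple(cap), radius=self.radius)
            cands.append(s.intersect(o, d))
        return _first_positive(*cands)

    def contains(self, p):
        w, L = self._axis
        oc = p - np.asarray(self.p0, float)
        h = np.clip(np.einsum("...i,i->...", oc, w), 0.0, L)
        closest = np.asarray(self.p0, float) + h[..., None] * w
        return ((p - closest) ** 2).sum(-1) <= self.radius**2


@dataclass(frozen=True)
class Cylinder(_Tube):
    """Finite cylinder with flat caps."""

    def intersect(self, o, d):
        (t1, t2), dw, ow, L = self._side_hits(o, d)
        cands = []
        for t in (t1, t2):
            h = ow + t * dw
            cands.append(np.where((h >= 0) & (h <= L), t, np.inf))
        w, _ = self._axis
        oc = o - np.asarray(self.p0, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            for h0 in (0.0, L):
                t = np.where(np.abs(dw) > 1e-12, (h0 - ow) / dw, np.inf)
                hit_pt = oc + t[..., None] * d
                rad2 = (
                    (hit_pt - np.einsum("...i,i->...", hit_pt, w)[..., None] * w) ** 2
                ).sum(-1)
                cands.append(np.where(rad2 <= self.radius**2, t, np.inf))
        return _first_positive(*cands)

    def contains(self, p):
        w, L = self._axis
        oc = p - np.asarray(self.p0, float)
        h = np.einsum("...i,i->...", oc, w)
        rad2 = ((oc - h[..., None] * w) ** 2).sum(-1)
        return (h >= 0) & (h <= L) & (rad2 <= self.radius**2)


@dataclass(frozen=True)
class Torus(_Solid):
    """Solid torus about ``axis``; ray hits found by sphere tracing its SDF."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    major_radius: float = 2.0
    minor_radius: float = 0.6

    def _sdf(self, p):
        w = np.asarray(self.axis, float)
        w = w / np.linalg.norm(w)
        q = p - np.asarray(self.center, float)
        h = np.einsum("...i,i->...", q, w)
        rad = np.sqrt(np.maximum(((q - h[..., None] * w) ** 2).sum(-1), 0.0))
        return np.sqrt((rad - self.major_radius) ** 2 + h * h) - self.minor_radius

    def intersect(self, o, d, eps: float = 1e-4, max_steps: int = 256):
        flat_o = np.broadcast_to(o, d.shape)
        # march only inside the bounding sphere (analytic entry/exit)
        bound = Sphere(center=self.center, radius=self.major_radius + self.minor_radius + eps)
        oc = flat_o - np.asarray(self.center, float)
        b = np.einsum("...i,...i->...", d, oc)
        c = np.einsum("...i,...i->...", oc, oc) - bound.radius**2
        disc = b * b - c
        inside_bound = disc >= 0
        sq = np.sqrt(np.where(inside_bound, disc, 0.0))
        shape = d.shape[:-1]
        t_out = np.full(shape, np.inf).reshape(-1)
        sel = np.flatnonzero(inside_bound.reshape(-1))
        o_a = flat_o.reshape(-1, 3)[sel]
        d_a = d.reshape(-1, 3)[sel]
        t_a = np.maximum((-b - sq).reshape(-1)[sel], 0.0)
        exit_a = (-b + sq).reshape(-1)[sel]
        active = np.arange(sel.size)
        for _ in range(max_steps):
            if active.size == 0:
                break
            p = o_a[active] + t_a[active, None] * d_a[active]
            dist = self._sdf(p)
            hit = dist < eps
            if hit.any():
                t_out[sel[active[hit]]] = t_a[active[hit]]
            t_a[active] += np.maximum(dist, eps * 0.5)
            active = active[~hit & (t_a[active] <= exit_a[active])]
        return t_out.reshape(shape)

    def contains(self, p):
        return self._sdf(p) <= 0.0

    def bounding_radius(self, about):
        return float(
            np.linalg.norm(np.asarray(self.center, float) - about)
            + self.major_radius
            + self.minor_radius
        )

    def volume_mm3(self) -> float:
        return 2.0 * math.pi**2 * self.major_radius * self.minor_radius**2


@dataclass(frozen=True)
class HalfSpace(_Solid):
    """Solid half-space below a plane; used for tilted-plane phantoms."""

    point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def intersect(self, o, d):
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        denom = np.einsum("...i,i->...", d, n)
        num = np.einsum("...i,i->...", np.asarray(self.point, float) - o, n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(denom) > 1e-12, num / denom, np.inf)
        inside = num > 0  # origin below the surface: ray starts inside
        t = np.where((t > 1e-9) & ~inside, t, np.inf)
        return t

    def contains(self, p):
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        return np.einsum("...i,i->...", p - np.asarray(self.point, float), n) <= 0

    def bounding_radius(self, about):
        return np.inf


@dataclass(frozen=True)
class Scene:
    """A set of analytic solids around a rotation centre."""

    solids: tuple[_Solid, ...]
    rotation_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.solids) == 0:
            raise InvalidInputError("scene must contain at least one solid")

    def bounding_radius(self) -> float:
        c = np.asarray(self.rotation_center, float)
        finite = [s.bounding_radius(c) for s in self.solids if np.isfinite(s.bounding_radius(c))]
        return max(finite) if finite else 5.0

    def contains(self, p) -> np.ndarray:
        out = np.zeros(np.asarray(p).shape[:-1], dtype=bool)
        for s in self.solids:
            out |= s.contains(np.asarray(p, float))
        return out


# ---------------------------------------------------------------------------
# camera geometry (single source of truth, reused by the visual-hull stage)


def camera_frame(pose: Pose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (right, up, forward) camera basis for a pose.

    ``forward`` looks from the camera toward the rotation centre
    (``-view_dir``); ``up`` is world +Z projected off the view axis, or
    world +X at the poles; ``right = forward x up_world`` completes a
    right-handed frame with image rows growing downward.
    """
    v = np.asarray(pose.view_dir, float)
    forward = -v
    up_world = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(v, up_world))) > 1.0 - 1e-9:
        up_world = np.array([1.0, 0.0, 0.0])
    right = np.cross(forward, up_world)
    right /= np.linalg.norm(right)
    up = np.cross(right, forward)
    return right, up, forward


def camera_center(
    pose: Pose,
    camera: CameraModel,
    rotation_center=(0.0, 0.0, 0.0),
    margin: float = 0.0,
    rail_offset_mm: float = 0.0,
) -> np.ndarray:
    """World position of the projection centre for a pose.

    ``rail_offset_mm`` moves the camera *toward* the scene (positive as the
    stack advances past the reference slice).
    """
    d = camera.focus_distance_mm * (1.0 + margin) - rail_offset_mm
    return np.asarray(rotation_center, float) + d * np.asarray(pose.view_dir, float)


def project_points(
    points: np.ndarray,
    pose: Pose,
    camera: CameraModel,
    rotation_center=(0.0, 0.0, 0.0),
    margin: float = 0.0,
    rail_offset_mm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pinhole projection of world points (mm) to pixel (col, row) + depth.

    Returns ``(uv, depth)`` where ``uv[..., 0]`` is the column, ``uv[..., 1]``
    the row, and ``depth`` the distance along the optical axis (mm).
    """
    right, up, forward = camera_frame(pose)
    C = camera_center(pose, camera, rotation_center, margin, rail_offset_mm)
    q = np.asarray(points, float) - C
    zc = q @ forward
    xc = q @ right
    yc = q @ up
    f = camera.focal_px
    ppx, ppy = camera.principal_point_px
    with np.errstate(divide="ignore", invalid="ignore"):
        u = ppx + f * xc / zc
        v = ppy - f * yc / zc
    return np.stack([u, v], axis=-1), zc


def _pixel_rays(pose: Pose, camera: CameraModel):
    right, up, forward = camera_frame(pose)
    f = camera.focal_px
    ppx, ppy = camera.principal_point_px
    cols = np.arange(camera.width_px)
    rows = np.arange(camera.height_px)
    cc, rr = np.meshgrid(cols, rows)
    d = (
        forward[None, None, :]
        + ((cc - ppx) / f)[..., None] * right[None, None, :]
        + ((ppy - rr) / f)[..., None] * up[None, None, :]
    )
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    return d, forward


# ---------------------------------------------------------------------------
# texture


def _value_noise(p: np.ndarray, scale_mm: float, seed: int) -> np.ndarray:
    """Smooth seeded value noise in [0, 1] over 3D points (trilinear lattice)."""

    def lattice(ix, iy, iz):
        h = (
            np.sin(
                ix * 127.1 + iy * 311.7 + iz * 74.7 + (seed % 65521) * 0.1031
            )
            * 43758.5453123
        )
        return h - np.floor(h)

    q = np.asarray(p, float) / max(scale_mm, 1e-6)
    i = np.floor(q)
    f = q - i
    f = f * f * (3.0 - 2.0 * f)  # smoothstep
    out = np.zeros(q.shape[:-1])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[..., 0] if dx else 1 - f[..., 0])
                    * (f[..., 1] if dy else 1 - f[..., 1])
                    * (f[..., 2] if dz else 1 - f[..., 2])
                )
                out += w * lattice(i[..., 0] + dx, i[..., 1] + dy, i[..., 2] + dz)
    return out


# ---------------------------------------------------------------------------
# rendering


def _trace(scene: Scene, origin: np.ndarray, dirs: np.ndarray):
    """Nearest-hit trace: per-pixel ray parameter and solid index (-1 miss)."""
    t_best = np.full(dirs.shape[:-1], np.inf)
    idx = np.full(dirs.shape[:-1], -1, dtype=int)
    o = np.broadcast_to(origin, dirs.shape)
    for k, solid in enumerate(scene.solids):
        t = solid.intersect(o, dirs)
        closer = t < t_best
        t_best = np.where(closer, t, t_best)
        idx = np.where(closer, k, idx)
    return t_best, idx


def render_view(
    scene: Scene,
    pose: Pose,
    camera: CameraModel,
    lighting: str = "front",
    seed: int = 0,
    margin: float = 0.0,
    rail_offset_mm: float = 0.0,
):
    """All-in-focus pinhole render from one camera position.

    Returns ``(image, depth, hit)``: RGB image in [0, 1], per-pixel depth
    along the optical axis in mm (inf where no solid is hit), and the hit
    (silhouette) mask.
    """
    if lighting not in ("front", "back"):
        raise InvalidParameterError(f"lighting must be 'front' or 'back', got {lighting!r}")
    dirs, forward = _pixel_rays(pose, camera)
    C = camera_center(pose, camera, scene.rotation_center, margin, rail_offset_mm)
    t, idx = _trace(scene, C, dirs)
    hit = np.isfinite(t)
    depth = np.where(hit, t * (dirs @ forward), np.inf)
    H, W = hit.shape
    if lighting == "back":
        img = np.where(hit[..., None], 0.0, 1.0) * np.ones((H, W, 3))
        return img, depth, hit
    img = np.full((H, W, 3), _BG_FRONT)
    pts = C + t[..., None] * dirs
    for k, solid in enumerate(scene.solids):
        sel = hit & (idx == k)
        if not sel.any():
            continue
        tex = 1.0
        if solid.texture_amp > 0:
            n = _value_noise(pts[sel], solid.texture_scale_mm, seed + 7919 * k)
            tex = 1.0 + solid.texture_amp * (2.0 * n - 1.0)
        col = np.clip(np.asarray(solid.albedo)[None, :] * np.atleast_1d(tex)[:, None], 0, 1)
        img[sel] = col
    return img, depth, hit


def render_ground_truth(
    scene: Scene, pose: Pose, camera: CameraModel, margin: float = 0.0, seed: int = 0
):
    """Reference-perspective ground truth: (sharp RGB, depth mm, silhouette)."""
    return render_view(scene, pose, camera, "front", seed=seed, margin=margin)


# ---------------------------------------------------------------------------
# focus stacks


@dataclass
class FocusStack:
    """Ordered focus-stack slices plus the rail positions they were taken at."""

    slices: list[np.ndarray]
    rail_positions_mm: np.ndarray
    lighting: str = "front"
    step_um: float = 0.0

    def __post_init__(self):
        if len(self.slices) != len(self.rail_positions_mm) or len(self.slices) < 1:
            raise InvalidInputError("slices and rail positions must match and be non-empty")
        rp = np.asarray(self.rail_positions_mm, float)
        if len(rp) > 1 and not (np.diff(rp) > 0).all():
            raise InvalidInputError("rail positions must be strictly increasing")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise InvalidInputError("all slices must share one shape")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def ref_index(self) -> int:
        return self.n_slices // 2


@dataclass(frozen=True)
class StackConfig:
    """How stacks are acquired: slice count, rail step, aperture, defocus cap.

    The default aperture makes the blur grown over one rail step roughly
    the acceptable circle of confusion (~2 px at the default step and
    focus distance), i.e. the rail step is matched to the depth of field,
    which is how a real scan chooses its step.
    """

    n_slices: int = 9
    step_um: float = 500.0
    aperture_mm: float = 20.0
    coc_max_px: float = 12.0
    margin: float = 0.0
    back_n_slices: int | None = None  # None: same as front


def _defocus_composite(
    sharp_rgb: np.ndarray,
    depth: np.ndarray,
    hit: np.ndarray,
    z_focus_mm: float,
    step_mm: float,
    k_px: float,
    coc_max_px: float,
    background: np.ndarray,
) -> np.ndarray:
    """Blur depth bins (one rail step wide) and composite far-to-near."""
    if k_px <= 0 or not hit.any():
        out = background.copy()
        out[hit] = sharp_rgb[hit]
        return out
    rel = np.where(hit, depth - z_focus_mm, 0.0)
    bins = np.round(rel / max(step_mm, 1e-6)).astype(int)
    out = background.copy()
    for b in sorted(np.unique(bins[hit]), reverse=True):  # far bins first
        sel = hit & (bins == b)
        z_b = z_focus_mm + b * step_mm
        coc = min(k_px * abs(b) * step_mm / max(z_b, 1e-6), coc_max_px)
        sigma = coc / 2.0
        alpha = sel.astype(float)
        col = sharp_rgb * alpha[..., None]
        if sigma > 0.05:
            alpha = ndimage.gaussian_filter(alpha, sigma)
            col = np.stack(
                [ndimage.gaussian_filter(col[..., c], sigma) for c in range(3)], axis=-1
            )
        out = col + (1.0 - alpha[..., None]) * out
    return np.clip(out, 0.0, 1.0)


def render_pose_stack(
    scene: Scene,
    pose: Pose,
    camera: CameraModel,
    n_slices: int,
    step_um: float,
    lighting: str = "front",
    seed: int = 0,
    aperture_mm: float = 20.0,
    coc_max_px: float = 12.0,
    margin: float = 0.0,
):
    """Render a focus stack for one pose, plus reference-view ground truth.

    Slice ``i`` is imaged with the camera advanced ``(i - n//2) * step``
    toward the scene from the reference position, keeping the lens focus
    distance fixed, so the in-focus plane sweeps near-to-far with ``i``.

    Returns ``(stack, gt_depth_mm, gt_silhouette)`` where the ground truth
    is rendered from the reference camera.
    """
    if n_slices < 1:
        raise InvalidParameterError("n_slices must be >= 1")
    zf = camera.focus_distance_mm
    k_px = camera.focal_px * aperture_mm / zf if aperture_mm > 0 else 0.0
    step_mm = step_um * 1e-3
    ref = n_slices // 2
    H, W = camera.height_px, camera.width_px
    bg = (
        np.ones((H, W, 3))
        if lighting == "back"
        else np.full((H, W, 3), _BG_FRONT)
    )
    slices = []
    for i in range(n_slices):
        off = (i - ref) * step_mm
        sharp, depth, hit = render_view(
            scene, pose, camera, lighting, seed=seed, margin=margin, rail_offset_mm=off
        )
        # plane in focus is at z_f from *this* camera position
        img = _defocus_composite(
            sharp, depth, hit, zf, step_mm, k_px, coc_max_px, bg
        )
        slices.append(img)
    stack = FocusStack(
        slices=slices,
        rail_positions_mm=np.arange(n_slices) * step_mm,
        lighting=lighting,
        step_um=step_um,
    )
    _, gt_depth, gt_sil = render_view(
        scene, pose, camera, "front", seed=seed, margin=margin, rail_offset_mm=0.0
    )
    return stack, gt_depth, gt_sil


def render_target_stack(
    camera: CameraModel,
    n_slices: int,
    step_um: float,
    grid_pitch_mm: float | None = None,
    n_dots: int = 7,
    dot_sigma_px: float | None = None,
) -> FocusStack:
    """Stack of a fixed flat dot grid at the reference focal plane.

    The implied projective coefficient is ``beta = step_um * 1e-3 / z_f``:
    as the camera advances the grid appears larger, with projected spacing
    ``spacing_ref / (1 - beta * (i - ref))`` — the measurement law the
    calibration fit inverts.  Dots are Gaussian blobs (the grid is treated
    as in focus throughout, the idealization the calibration procedure
    relies on).
    """
    zf = camera.focus_distance_mm
    f = camera.focal_px
    ppx, ppy = camera.principal_point_px
    ref = n_slices // 2
    step_mm = step_um * 1e-3
    if grid_pitch_mm is None:
        # grid fills ~70% of the frame regardless of magnification
        grid_pitch_mm = 0.7 * min(camera.width_px, camera.height_px) / (n_dots - 1) * zf / f
    if dot_sigma_px is None:
        dot_sigma_px = max(1.2, 0.1 * f * grid_pitch_mm / zf)
    half = (n_dots - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n_dots) - half, np.arange(n_dots) - half)
    cols = np.arange(camera.width_px)
    rows = np.arange(camera.height_px)
    cc, rr = np.meshgrid(cols, rows)
    slices = []
    for i in range(n_slices):
        dist = zf - (i - ref) * step_mm
        if dist <= 0:
            raise InvalidParameterError("rail overruns the target plane")
        spacing_px = f * grid_pitch_mm / dist
        img = np.ones((camera.height_px, camera.width_px))
        for a, b in zip(ii.ravel(), jj.ravel()):
            u = ppx + a * spacing_px
            v = ppy + b * spacing_px
            img -= np.exp(-(((cc - u) ** 2 + (rr - v) ** 2) / (2 * dot_sigma_px**2)))
        slices.append(np.clip(img, 0.0, 1.0))
    return FocusStack(
        slices=slices,
        rail_positions_mm=np.arange(n_slices) * step_mm,
        lighting="back",
        step_um=step_um,
    )


# ---------------------------------------------------------------------------
# scan writer


def demo_scene(seed: int = 0) -> Scene:
    """A textured sphere on a thin support pin, roughly beetle-sized."""
    return Scene(
        solids=(
            Sphere(center=(0, 0, 0), radius=3.0, albedo=(0.45, 0.32, 0.18),
                   texture_amp=0.4, texture_scale_mm=0.25),
            Capsule(p0=(0, 0, -6.5), p1=(0, 0, -2.0), radius=0.25,
                    albedo=(0.55, 0.55, 0.58), texture_amp=0.1),
        )
    )


def camera_for_scene(
    scene_radius_mm: float,
    width_px: int = 160,
    height_px: int | None = None,
    focus_distance_mm: float = 100.0,
    fill: float = 0.7,
    pixel_pitch_um: float = 5.5,
) -> CameraModel:
    """Camera whose field of view frames a scene of the given radius.

    ``fill`` is the fraction of the half-width the scene radius occupies.
    """
    if height_px is None:
        height_px = width_px
    # focal_px * R / z_f = fill * width/2  =>  magnification from focal_px
    focal_px = fill * (width_px / 2.0) * focus_distance_mm / scene_radius_mm
    magnification = focal_px * pixel_pitch_um / (focus_distance_mm * 1000.0)
    return CameraModel(
        pixel_pitch_um=pixel_pitch_um,
        width_px=width_px,
        height_px=height_px,
        magnification=magnification,
        focus_distance_mm=focus_distance_mm,
    )


def make_scan(
    scene: Scene,
    program: PoseProgram,
    camera: CameraModel,
    config: StackConfig,
    out_dir,
    seed: int = 0,
) -> Path:
    """Render and write a full synthetic scan to ``out_dir``.

    For every *accessible* pose a subdirectory ``pose_NNNN`` is written with
    the front-light stack, the back-light stack, and the reference-view
    ground truth (float32 depth TIFF + silhouette PNG); a manifest CSV keeps
    the bookkeeping.  Inaccessible poses are skipped.
    """
    import imageio.v3 as iio
    import tifffile

    if program.n_accessible < 1:
        raise InvalidInputError("pose program has no accessible poses")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    back_n = config.back_n_slices or config.n_slices
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["pose_index", "tilt_deg", "rot_deg", "front_path", "back_path",
             "n_slices", "step_um"]
        )
        for pose in program.accessible_poses:
            pdir = out / f"pose_{pose.index:04d}"
            pdir.mkdir(exist_ok=True)
            front, gt_depth, gt_sil = render_pose_stack(
                scene, pose, camera, config.n_slices, config.step_um, "front",
                seed=seed + pose.index, aperture_mm=config.aperture_mm,
                coc_max_px=config.coc_max_px, margin=config.margin,
            )
            back, _, _ = render_pose_stack(
                scene, pose, camera, back_n, config.step_um, "back",
                seed=seed + pose.index, aperture_mm=config.aperture_mm,
                coc_max_px=config.coc_max_px, margin=config.margin,
            )
            f_path, b_path = pdir / "front.tif", pdir / "back.tif"
            tifffile.imwrite(f_path, _to_u16(front.slices))
            tifffile.imwrite(b_path, _to_u16(back.slices))
            tifffile.imwrite(
                pdir / "gt_depth.tif",
                np.where(np.isfinite(gt_depth), gt_depth, 0.0).astype(np.float32),
            )
            iio.imwrite(pdir / "gt_mask.png", (gt_sil * 255).astype(np.uint8))
            w.writerow(
                [pose.index, f"{pose.tilt_deg:.6g}", f"{pose.rot_deg:.6g}",
                 f_path.name, b_path.name, config.n_slices, config.step_um]
            )
    return out


def _to_u16(slices) -> np.ndarray:
    return np.stack([(np.clip(s, 0, 1) * 65535 + 0.5).astype(np.uint16) for s in slices])


def read_stack_tiff(path, lighting: str = "front", step_um: float = 0.0) -> FocusStack:
    """Read a multi-page TIFF written by :func:`make_scan` back into a stack."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:  # single gray page
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4):  # single RGB page
        arr = arr[None]
    slices = [a.astype(float) / 65535.0 for a in arr]
    return FocusStack(
        slices=slices,
        rail_positions_mm=np.arange(len(slices)) * step_um * 1e-3,
        lighting=lighting,
        step_um=step_um,
    )
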