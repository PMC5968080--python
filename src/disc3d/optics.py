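"""Pinhole/rail geometry and focus-stack calibration.

During a stack, the camera (with its focus fixed at distance ``z_f``)
advances along a macro rail by one step ``dz`` per slice, so the plane in
focus sweeps through the specimen.  In-focus content is always imaged at
the same magnification, but from a *different* projection centre per slice,
so a naive best-focus composite is not a pinhole image.  Mapping the
in-focus content of slice ``i`` back to the perspective of a single
reference slice requires an isotropic rescale about the principal point by

    s_i = 1 / (1 + beta * (i - ref)),        beta = dz / z_f,

because the plane in focus at slice ``i`` sits ``(i - ref) * dz`` farther
from the reference projection centre.

``beta`` is measured once per optical configuration by photographing a
fixed flat dot grid through a whole stack.  For that *fixed* target the
projected spacing obeys the exact linear law

    spacing_ref / spacing_i = 1 - beta * (i - ref),

since the camera-to-target distance shrinks linearly as the rail advances.
``calibrate_from_target`` fits this one-parameter law; the fitted ``beta``
then feeds the projective per-slice scale above.  The two laws agree to
first order in ``beta * (i - ref)`` and share the single physical parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, DegenerateGeometryError, InvalidParameterError

__all__ = [
    "CameraModel",
    "StackCalibration",
    "object_pixel_size",
    "slice_scale",
    "calibrate_from_target",
    "detect_grid_spacing",
]


@dataclass(frozen=True)
class CameraModel:
    """Industrial camera + macro lens as a pinhole with fixed focus distance.

    Parameters
    ----------
    pixel_pitch_um
        Sensor pixel pitch in micrometres.
    width_px, height_px
        Sensor size in pixels.
    magnification
        Optical magnification at the in-focus plane (sensor mm per object mm).
    focus_distance_mm
        Distance ``z_f`` from the projection centre to the in-focus plane.
    principal_point_px
        (x, y) of the optical axis in pixel coordinates; defaults to the
        image centre.
    """

    pixel_pitch_um: float = 5.5
    width_px: int = 2048
    height_px: int = 2048
    magnification: float = 1.26
    focus_distance_mm: float = 100.0
    principal_point_px: tuple[float, float] | None = None

    def __post_init__(self):
        if self.pixel_pitch_um <= 0 or self.magnification <= 0 or self.focus_distance_mm <= 0:
            raise InvalidParameterError("camera parameters must be positive")
        pp = self.principal_point_px
        if pp is None:
            pp = ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)
            object.__setattr__(self, "principal_point_px", pp)
        if not (0 <= pp[0] < self.width_px and 0 <= pp[1] < self.height_px):
            raise InvalidParameterError("principal point must lie inside the image")

    @property
    def object_pixel_um(self) -> float:
        """Object-side pixel size (digital resolution) in micrometres."""
        return object_pixel_size(self.pixel_pitch_um, self.magnification)

    @property
    def focal_px(self) -> float:
        """Pinhole focal length in pixels: an object offset x at distance
        z_f projects to ``focal_px * x / z_f`` pixels off the principal
        point, which equals ``x * magnification / pitch`` at the in-focus
        plane."""
        return self.magnification * self.focus_distance_mm * 1000.0 / self.pixel_pitch_um


def object_pixel_size(pitch_um: float, magnification: float) -> float:
    """Object-side pixel size in µm: sensor pitch divided by magnification.

    At the paper-standard 5.5 µm pitch and x1.26 this is 4.37 µm.
    """
    if pitch_um <= 0 or magnification <= 0:
        raise InvalidParameterError("pitch and magnification must be positive")
    return pitch_um / magnification


@dataclass
class StackCalibration:
    """Per-slice perspective scale model of a focus-stack acquisition."""

    n_slices: int
    step_um: float
    ref_index: int
    beta: float
    residual_rms: float = 0.0
    measured_scales: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not (0 <= self.ref_index < self.n_slices):
            raise InvalidParameterError("ref_index must be a valid slice index")

    @property
    def scales(self) -> np.ndarray:
        """EDOF rescale factor s_i for every slice (s_ref = 1 exactly)."""
        return np.array([slice_scale(i, self) for i in range(self.n_slices)])

    @classmethod
    def from_geometry(
        cls, n_slices: int, step_um: float, focus_distance_mm: float, ref_index: int | None = None
    ) -> "StackCalibration":
        """Calibration predicted from known rail step and focus distance."""
        if ref_index is None:
            ref_index = n_slices // 2
        beta = (step_um * 1e-3) / focus_distance_mm
        return cls(n_slices, step_um, ref_index, beta)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "n_slices": int(self.n_slices),
                    "step_um": float(self.step_um),
                    "ref_index": int(self.ref_index),
                    "beta": float(self.beta),
                    "residual_rms": float(self.residual_rms),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "StackCalibration":
        import yaml

        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(
            n_slices=int(d["n_slices"]),
            step_um=float(d["step_um"]),
            ref_index=int(d["ref_index"]),
            beta=float(d["beta"]),
            residual_rms=float(d.get("residual_rms", 0.0)),
        )


def slice_scale(i: int, cal: StackCalibration) -> float:
    """Projective rescale factor mapping slice ``i`` to the reference
    perspective: ``1 / (1 + beta * (i - ref_index))``."""
    if not (0 <= i < cal.n_slices):
        raise InvalidParameterError(f"slice index {i} outside [0, {cal.n_slices})")
    denom = 1.0 + cal.beta * (i - cal.ref_index)
    if denom <= 0:
        raise DegenerateGeometryError(
            f"degenerate geometry at slice {i}: 1 + beta*(i-ref) = {denom:.4g}"
        )
    return 1.0 / denom


def detect_grid_spacing(image: np.ndarray, min_dots: int = 4) -> float:
    """Mean nearest-neighbour spacing (px) of the dots in a grid image.

    Dots are assumed darker than the background.  Rough centroids come from
    labelling the below-Otsu region; each is then refined by a few
    mean-shift iterations of a Gaussian-windowed darkness-weighted centroid,
    which removes the pixel-grid truncation bias of plain thresholded
    centroids (the window tracks the estimate, not the pixel lattice).  The
    spacing statistic is the mean distance from each dot to its nearest
    neighbour, which for a square grid equals the grid pitch.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() - img.min() < 1e-9:
        raise CalibrationError("uniform image: no dots detected")
    mask = img < threshold_otsu(img)
    labels, n = ndimage.label(mask)
    if n < min_dots:
        raise CalibrationError(f"only {n} dots detected (need >= {min_dots})")
    dark = img.max() - img
    rough = np.array(
        ndimage.center_of_mass(np.where(mask, dark, 0.0), labels, range(1, n + 1))
    )
    areas = ndimage.sum_labels(np.ones_like(img), labels, range(1, n + 1))
    H, W = img.shape
    cent = np.empty_like(rough)
    for j, ((cy, cx), area) in enumerate(zip(rough, areas)):
        sw = 0.85 * math.sqrt(area / math.pi)  # ~dot sigma; excludes neighbours
        half = max(3, int(math.ceil(4.0 * sw)))
        for _ in range(4):
            r0, r1 = max(0, int(cy) - half), min(H, int(cy) + half + 1)
            c0, c1 = max(0, int(cx) - half), min(W, int(cx) + half + 1)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            w = dark[r0:r1, c0:c1] * np.exp(
                -((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sw * sw)
            )
            s = w.sum()
            if s <= 0:
                break
            cy, cx = float((w * rr).sum() / s), float((w * cc).sum() / s)
        cent[j] = (cy, cx)
    d2 = ((cent[:, None, :] - cent[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min(axis=1)).mean())


def calibrate_from_target(
    target_stack, grid_pitch_mm: float | None = None, ref_index: int | None = None
) -> StackCalibration:
    """Fit the perspective-scale model from a stack of a fixed dot grid.

    Parameters
    ----------
    target_stack
        A :class:`~disc3d.synth.FocusStack` (or any object with ``slices``
        and ``step_um``) imaging a fixed flat dot grid in every slice.
    grid_pitch_mm
        Metric grid pitch; only recorded, not needed for the fit.

    Notes
    -----
    The measured per-slice ratio ``r_i = spacing_ref / spacing_i`` follows
    the exact linear law ``r_i = 1 - beta * (i - ref)`` for a fixed target
    and a linear rail, so ``beta`` is obtained by one-dimensional least
    squares; the residual RMS of that fit is stored.
    """
    slices = list(target_stack.slices)
    n = len(slices)
    if ref_index is None:
        ref_index = n // 2
    spacing = np.array([detect_grid_spacing(s) for s in slices])
    r = spacing[ref_index] / spacing
    di = np.arange(n) - ref_index
    denom = float((di * di).sum())
    if denom == 0:
        beta = 0.0
    else:
        beta = float(-((r - 1.0) * di).sum() / denom)
    resid = r - (1.0 - beta * di)
    step_um = getattr(target_stack, "step_um", 0.0)
    return StackCalibration(
        n_slices=n,
        step_um=float(step_um),
        ref_index=ref_index,
        beta=beta,
        residual_rms=float(np.sqrt((resid**2).mean())),
        measured_scales=r,
    )
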