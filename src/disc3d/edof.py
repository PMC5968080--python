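"""Calibrated extended-depth-of-field (EDOF) compositing.

The composite must be consistent with a *single* pinhole perspective so it
can feed photogrammetry.  Because the camera moves between slices, each
slice is first rescaled about the principal point by its calibrated
perspective factor ``s_i`` (see :mod:`disc3d.optics`); only then is the
usual depth-from-focus machinery applied: per-pixel sharpness, winner-take-
all slice selection with sub-slice parabolic refinement, median smoothing
of the depth-index map, and a linear blend of the two bracketing slices.
Pixels with no focus response anywhere in the stack (featureless
background) are flagged and filled from the reference slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError
from .optics import StackCalibration, slice_scale
from .synth import FocusStack

__all__ = [
    "DepthIndexMap",
    "EdofResult",
    "EdofParams",
    "focus_measure",
    "rescale_to_reference",
    "compose_edof",
]


@dataclass
class DepthIndexMap:
    """Fractional best-focus slice index per pixel, with confidence."""

    values: np.ndarray
    confidence: np.ndarray
    background_flag: np.ndarray


@dataclass
class EdofResult:
    """Composite image plus the depth-index map it was blended from."""

    image: np.ndarray
    depth: DepthIndexMap
    pose_index: int = -1
    calibration: StackCalibration | None = None


@dataclass(frozen=True)
class EdofParams:
    """Tunables of the compositing stage (defaults are the tested ones)."""

    window_px: int = 9
    median_px: int = 5
    confidence_floor: float = 1e-4  # fraction of the max confidence
    use_otsu_background: bool = True


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return img @ np.array([0.299, 0.587, 0.114])
    return np.asarray(img, dtype=float)


def focus_measure(image: np.ndarray, window_px: int = 9) -> np.ndarray:
    """Smoothed-Laplacian focus measure, box-summed over ``window_px``.

    Gaussian pre-smooth (sigma 1 px) suppresses sensor noise, the absolute
    Laplacian responds to in-focus detail, and the box sum pools the
    response so untextured pixels inherit sharpness from their surround.
    Constant images map to exactly zero.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise InvalidParameterError("window_px must be odd and >= 3")
    g = _to_gray(image)
    if window_px > min(g.shape):
        raise InvalidParameterError("window larger than image")
    smooth = ndimage.gaussian_filter(g, sigma=1.0)
    resp = np.abs(ndimage.laplace(smooth))
    return ndimage.uniform_filter(resp, size=window_px) * window_px**2


def rescale_to_reference(
    slice_image: np.ndarray,
    i: int,
    cal: StackCalibration,
    principal_point: tuple[float, float],
    return_valid: bool = False,
):
    """Isotropically rescale a slice about the principal point by ``s_i``.

    Bilinear interpolation; areas that map outside the source are filled
    with the edge value (and reported in the validity mask on request).
    The output has the same shape as the input, and ``s = 1`` is an exact
    no-op.
    """
    s = slice_scale(i, cal)
    img = np.asarray(slice_image, dtype=float)
    if s == 1.0:
        valid = np.ones(img.shape[:2], dtype=bool)
        return (img.copy(), valid) if return_valid else img.copy()
    ppx, ppy = principal_point
    H, W = img.shape[:2]
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    src_r = ppy + (rr - ppy) / s
    src_c = ppx + (cc - ppx) / s
    valid = (src_r >= 0) & (src_r <= H - 1) & (src_c >= 0) & (src_c <= W - 1)
    coords = np.stack([src_r, src_c])
    if img.ndim == 3:
        out = np.stack(
            [
                ndimage.map_coordinates(img[..., c], coords, order=1, mode="nearest")
                for c in range(img.shape[2])
            ],
            axis=-1,
        )
    else:
        out = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return (out, valid) if return_valid else out


def compose_edof(
    stack: FocusStack,
    cal: StackCalibration,
    params: EdofParams | None = None,
    pose_index: int = -1,
    principal_point: tuple[float, float] | None = None,
) -> EdofResult:
    """Merge a focus stack into one perspective-consistent EDOF image.

    Steps: rescale every slice to the reference perspective; per-pixel
    focus measure; winner-take-all slice selection (ties resolved toward
    the camera-near slice, which is occlusion-correct for opaque
    specimens); parabolic sub-slice refinement; 5x5 median smoothing of the
    index map; linear blend of the two bracketing slices; low-confidence
    pixels flagged background and filled from the reference slice.
    """
    if params is None:
        params = EdofParams()
    n = stack.n_slices
    if n == 0:
        raise InvalidInputError("empty stack")
    if n != cal.n_slices:
        raise InvalidInputError(
            f"stack has {n} slices but calibration expects {cal.n_slices}"
        )
    first = stack.slices[0]
    H, W = first.shape[:2]
    if principal_point is None:
        principal_point = ((W - 1) / 2.0, (H - 1) / 2.0)

    rescaled = [
        rescale_to_reference(stack.slices[i], i, cal, principal_point)
        for i in range(n)
    ]
    measures = np.stack([focus_measure(r, params.window_px) for r in rescaled])

    best = measures.argmax(axis=0)  # first max wins: camera-near tie-break
    confidence = measures.max(axis=0)

    # parabolic refinement around the winning slice
    frac = best.astype(float)
    if n >= 3:
        inner = (best > 0) & (best < n - 1)
        rr, cc = np.nonzero(inner)
        b = best[rr, cc]
        m0 = measures[b - 1, rr, cc]
        m1 = measures[b, rr, cc]
        m2 = measures[b + 1, rr, cc]
        denom = m0 - 2 * m1 + m2
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (m0 - m2) / denom, 0.0)
        frac[rr, cc] = b + np.clip(delta, -0.5, 0.5)

    if params.median_px > 1 and min(H, W) >= params.median_px:
        frac = ndimage.median_filter(frac, size=params.median_px)
    frac = np.clip(frac, 0.0, n - 1.0)

    # background: no focus response anywhere in the stack
    floor = params.confidence_floor * max(float(confidence.max()), 1e-30)
    thr = floor
    if params.use_otsu_background and confidence.max() > confidence.min():
        from skimage.filters import threshold_otsu

        thr = max(float(threshold_otsu(confidence)), floor)
    background = confidence < thr

    lo = np.floor(frac).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = (frac - lo)[..., None] if first.ndim == 3 else (frac - lo)
    cube = np.stack(rescaled)
    idx_lo = lo[None, ..., None] if first.ndim == 3 else lo[None]
    idx_hi = hi[None, ..., None] if first.ndim == 3 else hi[None]
    img_lo = np.take_along_axis(cube, np.broadcast_to(idx_lo, (1,) + first.shape), 0)[0]
    img_hi = np.take_along_axis(cube, np.broadcast_to(idx_hi, (1,) + first.shape), 0)[0]
    image = (1.0 - w) * img_lo + w * img_hi
    image[background] = rescaled[cal.ref_index][background]
    image = np.clip(image, 0.0, 1.0)

    depth = DepthIndexMap(values=frac, confidence=confidence, background_flag=background)
    return EdofResult(image=image, depth=depth, pose_index=pose_index, calibration=cal)
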