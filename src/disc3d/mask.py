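"""Back-light silhouette segmentation and alpha-channel masking.

Under back-light the specimen appears dark against the evenly lit white
dome, so a global threshold separates it cleanly.  The binary silhouette
is tidied with a small morphological closing, hole filling, and a minimum-
area filter, then stored as the alpha channel of the front-light EDOF
image; downstream photogrammetry reads the mask straight from the PNG.
The opaque support pin stays inside the mask by design — it is removed
during 3D modelling, not here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import InvalidInputError

__all__ = ["SilhouetteMask", "MaskParams", "segment_backlight", "apply_alpha", "iou"]


@dataclass(frozen=True)
class MaskParams:
    threshold: float | None = None  # None: Otsu
    closing_radius_px: int = 2
    min_area_px: int = 50


@dataclass
class SilhouetteMask:
    """Boolean specimen silhouette with simple component statistics."""

    mask: np.ndarray
    area_px: int
    n_components: int

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "SilhouetteMask":
        mask = np.asarray(mask, dtype=bool)
        _, n = ndimage.label(mask)
        return cls(mask=mask, area_px=int(mask.sum()), n_components=int(n))


def segment_backlight(
    back_edof: np.ndarray, params: MaskParams | None = None
) -> SilhouetteMask:
    """Segment the specimen from a back-light image (dark object, bright bg).

    Global threshold (Otsu unless a fixed value is given), closing with a
    radius-2 disk, hole filling, and removal of components below
    ``min_area_px``.  A perfectly uniform image yields an empty mask and a
    warning rather than an error.
    """
    if params is None:
        params = MaskParams()
    img = np.asarray(back_edof, dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    if img.max() - img.min() < 1e-12:
        warnings.warn("uniform back-light image: empty mask", stacklevel=2)
        return SilhouetteMask.from_array(np.zeros(img.shape, dtype=bool))
    thr = params.threshold if params.threshold is not None else threshold_otsu(img)
    mask = img < thr
    if params.closing_radius_px > 0:
        mask = ndimage.binary_closing(
            mask, structure=disk(params.closing_radius_px), border_value=0
        )
    mask = ndimage.binary_fill_holes(mask)
    if params.min_area_px > 0:
        labels, n = ndimage.label(mask)
        if n:
            sizes = ndimage.sum_labels(mask, labels, range(1, n + 1))
            small = np.flatnonzero(sizes < params.min_area_px) + 1
            if small.size:
                mask &= ~np.isin(labels, small)
    return SilhouetteMask.from_array(mask)


def apply_alpha(front_edof: np.ndarray, mask: SilhouetteMask) -> np.ndarray:
    """Attach the silhouette as the alpha channel of an RGB image.

    Returns a uint8 RGBA array: alpha 255 on the specimen, 0 on background,
    RGB quantized from [0, 1] but otherwise untouched, so the result
    round-trips losslessly through PNG.
    """
    img = np.asarray(front_edof)
    if img.ndim != 3 or img.shape[2] < 3:
        raise InvalidInputError("front image must be H x W x 3")
    if img.shape[:2] != mask.mask.shape:
        raise InvalidInputError(
            f"shape mismatch: image {img.shape[:2]} vs mask {mask.mask.shape}"
        )
    if img.dtype == np.uint8:
        rgb = img[..., :3]
    else:
        rgb = (np.clip(img[..., :3], 0, 1) * 255 + 0.5).astype(np.uint8)
    alpha = np.where(mask.mask, 255, 0).astype(np.uint8)
    return np.dstack([rgb, alpha])


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
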