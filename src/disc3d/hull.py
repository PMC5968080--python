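"""Shape-from-silhouette visual-hull reconstruction.

The visual hull is the intersection of the visual cones cast by the
silhouettes: a voxel survives only if its centre projects inside every
view's image frame *and* inside that view's silhouette.  The hull contains
the true object by construction (silhouette rays are tangent to it), so
its volume upper-bounds the object volume, and concavities that never
appear on a silhouette — indentations, the inner waist of a torus —
cannot be recovered.

Camera geometry is exactly the synthetic scanner's reference perspective
(:func:`disc3d.synth.project_points`), so hulls carved from rendered or
EDOF-composited masks line up with the scene in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .mask import SilhouetteMask
from .optics import CameraModel
from .poses import Pose
from .synth import project_points

__all__ = ["VoxelGrid", "carve", "extract_surface"]


@dataclass
class VoxelGrid:
    """Axis-aligned occupancy grid in millimetres."""

    origin_mm: np.ndarray  # centre of voxel (0,0,0)
    voxel_mm: float
    occupancy: np.ndarray  # boolean, shape (nx, ny, nz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_occupied * self.voxel_mm**3

    def centers(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return self.origin_mm + self.voxel_mm * np.stack(
            [ix, iy, iz], axis=-1
        ).reshape(-1, 3)

    @classmethod
    def empty(cls, half_extent_mm: float, resolution: int, center=(0.0, 0.0, 0.0)):
        """Cubic grid of ``resolution**3`` voxels spanning ±half_extent."""
        voxel = 2.0 * half_extent_mm / resolution
        origin = np.asarray(center, float) - half_extent_mm + voxel / 2.0
        occ = np.ones((resolution, resolution, resolution), dtype=bool)
        return cls(origin_mm=origin, voxel_mm=voxel, occupancy=occ)


def carve(
    masks: dict[int, SilhouetteMask] | list[SilhouetteMask],
    poses: list[Pose],
    camera: CameraModel,
    half_extent_mm: float,
    resolution: int = 128,
    rotation_center=(0.0, 0.0, 0.0),
    margin: float = 0.0,
) -> VoxelGrid:
    """Carve a voxel grid with one silhouette per pose.

    ``masks`` maps ``pose.index`` to its silhouette (or is a list parallel
    to ``poses``).  Voxel centres projecting outside any image frame are
    carved away too (the specimen is assumed fully framed in every view).
    """
    if len(poses) == 0:
        raise InvalidInputError("need at least one pose to carve")
    if not isinstance(masks, dict):
        if len(masks) != len(poses):
            raise InvalidInputError("one mask per pose required")
        masks = {p.index: m for p, m in zip(poses, masks)}
    grid = VoxelGrid.empty(half_extent_mm, resolution, center=rotation_center)
    pts = grid.centers()
    alive = np.ones(len(pts), dtype=bool)
    for pose in poses:
        m = masks[pose.index]
        sil = m.mask if isinstance(m, SilhouetteMask) else np.asarray(m, bool)
        H, W = sil.shape
        uv, depth = project_points(
            pts[alive], pose, camera, rotation_center=rotation_center, margin=margin
        )
        col = np.round(uv[:, 0]).astype(int)
        row = np.round(uv[:, 1]).astype(int)
        ok = (depth > 0) & (col >= 0) & (col < W) & (row >= 0) & (row < H)
        keep = np.zeros(ok.shape, dtype=bool)
        keep[ok] = sil[row[ok], col[ok]]
        alive[alive.nonzero()[0]] = keep
        if not alive.any():
            break
    grid.occupancy = alive.reshape(grid.shape)
    return grid


def extract_surface(grid: VoxelGrid):
    """Marching-cubes isosurface of the occupancy at level 0.5.

    Returns a watertight, outward-oriented :class:`trimesh.Trimesh` in
    millimetre coordinates.  The occupancy is zero-padded (so hulls touching
    the grid boundary still close) and upsampled 2x nearest-neighbour first,
    which keeps the isosurface near the voxel-cell boundary instead of
    collapsing isolated voxels to octahedra.
    """
    import trimesh
    from scipy import ndimage
    from skimage.measure import marching_cubes

    if grid.n_occupied == 0:
        raise InvalidInputError("cannot extract a surface from an empty grid")
    vol = ndimage.zoom(np.pad(grid.occupancy.astype(np.float32), 1), 2, order=0)
    verts, faces, _, _ = marching_cubes(vol, level=0.5,
                                        spacing=(grid.voxel_mm / 2.0,) * 3)
    # upsampled sample k sits at original index (k - 0.5)/2; subtract the pad
    verts = verts - 1.25 * grid.voxel_mm + grid.origin_mm
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    trimesh.repair.fix_normals(mesh)
    return mesh
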