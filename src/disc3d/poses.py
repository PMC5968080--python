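"""Spherical pose programs for the two-axis gimbal.

A *pose program* is the preassigned set of (tilt, rotation) orientations
under which a pinned specimen is imaged so that views cover the whole
sphere at an approximately constant angular spacing.  Tilt rings are laid
out every ``spacing_deg`` from the lower to the upper pole, and the ring
at tilt theta carries ``round((360/spacing) * cos(theta))`` equally spaced
rotation angles, so the azimuthal spacing tracks the shrinking circumference
of the ring.  Each pole is a single pose.  With the standard 10 deg spacing
this yields 412 poses.

Poses whose view direction falls too close to the support-pin axis cannot
be imaged (the pin and its holder block the view); they are flagged
inaccessible by a symmetric double-cone exclusion.  A 15 deg half-angle
cone about the pin axis removes 14 of the 412 standard poses, leaving 398.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Pose",
    "PoseProgram",
    "generate_pose_program",
    "angular_distance",
    "mean_nn_distance",
    "apply_exclusion",
    "write_pose_csv",
    "read_pose_csv",
]

PIN_AXIS = np.array([0.0, 0.0, 1.0])


def view_direction(tilt_deg: float, rot_deg: float) -> np.ndarray:
    """Unit view direction for gimbal angles, in the laboratory frame.

    The pin axis is +Z; tilt is elevation from the equatorial plane and
    rotation is azimuth about the pin (right-handed).
    """
    t = math.radians(tilt_deg)
    r = math.radians(rot_deg)
    return np.array(
        [math.cos(t) * math.cos(r), math.cos(t) * math.sin(r), math.sin(t)]
    )


@dataclass(frozen=True)
class Pose:
    """One gimbal orientation: the direction from which the camera views."""

    index: int
    tilt_deg: float
    rot_deg: float
    view_dir: np.ndarray = field(repr=False)
    accessible: bool = True

    @classmethod
    def from_angles(
        cls, index: int, tilt_deg: float, rot_deg: float, accessible: bool = True
    ) -> "Pose":
        return cls(index, tilt_deg, rot_deg, view_direction(tilt_deg, rot_deg), accessible)


@dataclass(frozen=True)
class PoseProgram:
    """An ordered pose list with its nominal spacing and exclusion cone."""

    spacing_deg: float
    poses: tuple[Pose, ...]
    exclusion_cone_deg: float = 0.0

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    @property
    def accessible_poses(self) -> tuple[Pose, ...]:
        return tuple(p for p in self.poses if p.accessible)

    @property
    def n_accessible(self) -> int:
        return sum(1 for p in self.poses if p.accessible)

    def view_matrix(self) -> np.ndarray:
        """(n, 3) array of view directions, in pose order."""
        return np.array([p.view_dir for p in self.poses])

    @classmethod
    def from_angles(
        cls,
        tilt_rot_pairs,
        spacing_deg: float = float("nan"),
        exclusion_cone_deg: float = 0.0,
    ) -> "PoseProgram":
        """Build a custom program from explicit (tilt, rot) pairs."""
        poses = tuple(
            Pose.from_angles(i, t, r) for i, (t, r) in enumerate(tilt_rot_pairs)
        )
        return cls(spacing_deg, poses, exclusion_cone_deg)


def generate_pose_program(spacing_deg: float) -> PoseProgram:
    """Generate the standard all-sphere pose program.

    Rings are ordered from the lower pole upward, each ring by ascending
    rotation angle, so manifests are reproducible.

    Parameters
    ----------
    spacing_deg
        Nominal angular distance between neighbouring poses; must divide
        180 evenly and lie in [1, 90].
    """
    if not (1.0 <= spacing_deg <= 90.0):
        raise InvalidParameterError(f"spacing_deg must be in [1, 90], got {spacing_deg}")
    n_steps = 180.0 / spacing_deg
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidParameterError(
            f"spacing_deg must divide 180 evenly, got {spacing_deg}"
        )
    poses: list[Pose] = []
    per_turn = 360.0 / spacing_deg
    for k in range(int(round(n_steps)) + 1):
        tilt = -90.0 + k * spacing_deg
        if abs(abs(tilt) - 90.0) < 1e-9:
            n_rot = 1
        else:
            n_rot = int(round(per_turn * math.cos(math.radians(tilt))))
        for j in range(n_rot):
            rot = j * (360.0 / n_rot)
            poses.append(Pose.from_angles(len(poses), tilt, rot))
    return PoseProgram(spacing_deg=spacing_deg, poses=tuple(poses))


def angular_distance(a: Pose, b: Pose) -> float:
    """Great-circle angle between two view directions, in degrees."""
    d = float(np.clip(np.dot(a.view_dir, b.view_dir), -1.0, 1.0))
    return math.degrees(math.acos(d))


def mean_nn_distance(program: PoseProgram) -> float:
    """Mean over poses of the angular distance to the nearest other pose."""
    if len(program) < 2:
        raise InvalidInputError("need at least 2 poses for a nearest-neighbour spacing")
    v = program.view_matrix()
    dots = np.clip(v @ v.T, -1.0, 1.0)
    np.fill_diagonal(dots, -1.0)  # exclude self
    nn = np.degrees(np.arccos(dots.max(axis=1)))
    return float(nn.mean())


def apply_exclusion(
    program: PoseProgram, cone_deg: float, axis: np.ndarray | None = None
) -> PoseProgram:
    """Flag poses within a symmetric double cone of the pin axis inaccessible.

    A pose is excluded when its view direction lies within ``cone_deg`` of
    either +axis or -axis; all other accessibility flags are left unchanged.
    """
    if axis is None:
        axis = PIN_AXIS
    axis = np.asarray(axis, dtype=float)
    if not (0.0 <= cone_deg <= 90.0):
        raise InvalidParameterError(f"cone_deg must be in [0, 90], got {cone_deg}")
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise InvalidParameterError("exclusion axis must be a unit vector")
    new = []
    for p in program.poses:
        ang = math.degrees(
            math.acos(float(np.clip(abs(np.dot(p.view_dir, axis)), 0.0, 1.0)))
        )
        if ang <= cone_deg + 1e-9:
            p = replace(p, accessible=False)
        new.append(p)
    return PoseProgram(program.spacing_deg, tuple(new), exclusion_cone_deg=cone_deg)


def write_pose_csv(program: PoseProgram, path) -> None:
    """Write the pose manifest: index, tilt_deg, rot_deg, accessible."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "tilt_deg", "rot_deg", "accessible"])
        for p in program.poses:
            w.writerow([p.index, f"{p.tilt_deg:.6g}", f"{p.rot_deg:.6g}", int(p.accessible)])


def read_pose_csv(path, spacing_deg: float = float("nan")) -> PoseProgram:
    import csv

    poses = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            poses.append(
                Pose.from_angles(
                    int(row["index"]),
                    float(row["tilt_deg"]),
                    float(row["rot_deg"]),
                    bool(int(row["accessible"])),
                )
            )
    return PoseProgram(spacing_deg, tuple(poses))
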