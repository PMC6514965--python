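"""Rigid-body pose generation for capsomer-pair scans.

One capsomer stays fixed while the other is manipulated in a plane parallel to
the local (flat) capsid surface.  Four operations generate pose series:

* ``shift_away``     -- translate along the line joining the two mass centers,
* ``shift_perp``     -- translate perpendicular to that line (in-plane), after
                        a fixed standoff along it,
* ``spin``           -- rotate the moving capsomer about its own center,
* ``rotate_around``  -- orbit the moving capsomer rigidly about the fixed one.

Every pose is an exact isometry: intra-capsomer distances are preserved to
machine precision.  Angles follow the right-hand rule about the plane normal;
the scan parameter is the added displacement (A) or rotation (degrees)
relative to the native pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .errors import GeometryError
from .model import CapsomerModel
from . import structure_io

OPERATIONS = ("shift_away", "shift_perp", "spin", "rotate_around")


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis (Rodrigues)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


@dataclass
class CapsomerPair:
    """A fixed and a moving capsomer plus the scan frame.

    ``plane_normal`` defaults to the fixed capsomer's pseudo-3-fold axis
    (capsomers sit normal to the capsid surface).  ``native_axis`` is the unit
    vector from the fixed to the moving center of mass projected into the
    scan plane.
    """

    fixed: CapsomerModel
    moving: CapsomerModel
    plane_normal: Optional[np.ndarray] = None
    native_axis: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.plane_normal is None:
            self.plane_normal = structure_io.principal_c3_axis(self.fixed)
        nrm = np.asarray(self.plane_normal, dtype=float)
        self.plane_normal = nrm / np.linalg.norm(nrm)
        sep = self.moving.center_of_mass - self.fixed.center_of_mass
        in_plane = sep - np.dot(sep, self.plane_normal) * self.plane_normal
        norm = np.linalg.norm(in_plane)
        if norm < 1e-9:
            raise GeometryError(
                "capsomer centers coincide in the scan plane; native axis undefined"
            )
        self.native_axis = in_plane / norm

    @property
    def native_separation(self) -> float:
        return float(np.linalg.norm(
            self.moving.center_of_mass - self.fixed.center_of_mass))


@dataclass
class Pose:
    """A rigid transform x -> R (x - pivot) + pivot + t with its scan bookkeeping."""

    rotation: np.ndarray
    translation: np.ndarray
    pivot: np.ndarray
    scan_param: float
    operation: str

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.pivot = np.asarray(self.pivot, dtype=float).reshape(3)
        _check_rotation(self.rotation)

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        return (points - self.pivot) @ self.rotation.T + self.pivot + self.translation


def _check_rotation(R: np.ndarray) -> None:
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not math.isclose(
        float(np.linalg.det(R)), 1.0, abs_tol=1e-8
    ):
        raise ValueError("rotation matrix must be orthonormal with det +1")


def apply_pose(model: CapsomerModel, pose: Pose) -> CapsomerModel:
    """Transform a model by a pose; charges/radii/identity are untouched."""
    _check_rotation(pose.rotation)
    return model.with_positions(pose.apply_to_points(model.positions))


@dataclass
class PoseSeries:
    """Ordered poses from one scan operation over a regular grid."""

    pair: CapsomerPair
    poses: List[Pose]
    grid: tuple  # (start, stop, step) in the operation's unit
    operation: str

    def __len__(self) -> int:
        return len(self.poses)

    def moving_models(self):
        """Yield the moving capsomer transformed by each pose, in scan order."""
        for pose in self.poses:
            yield apply_pose(self.pair.moving, pose)


def _grid(start: float, stop: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be > 0")
    if stop < start:
        raise ValueError("stop must be >= start")
    count = int(math.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(count)


def shift_away(pair: CapsomerPair, start: float, stop: float, step: float) -> PoseSeries:
    """Translate the moving capsomer away along the center-of-mass line.

    Pose i adds (start + i*step) A of separation along the native axis; the
    printed scan of 5..40 A in 1 A steps yields 36 poses.
    """
    poses = [
        Pose(np.eye(3), d * pair.native_axis, np.zeros(3), float(d), "shift_away")
        for d in _grid(start, stop, step)
    ]
    return PoseSeries(pair, poses, (start, stop, step), "shift_away")


def shift_perpendicular(pair: CapsomerPair, start: float, stop: float, step: float,
                        standoff: float = 20.0) -> PoseSeries:
    """Slide the moving capsomer sideways after a standoff along the axis.

    The perpendicular direction is plane_normal x native_axis (in-plane); the
    scan parameter is the signed perpendicular offset in A.
    """
    if standoff < 0:
        raise ValueError("standoff must be >= 0")
    perp = np.cross(pair.plane_normal, pair.native_axis)
    perp = perp / np.linalg.norm(perp)
    poses = [
        Pose(np.eye(3), standoff * pair.native_axis + x * perp, np.zeros(3),
             float(x), "shift_perp")
        for x in _grid(start, stop, step)
    ]
    return PoseSeries(pair, poses, (start, stop, step), "shift_perp")


def spin(pair: CapsomerPair, start: float, stop: float, step: float,
         standoff: float = 20.0) -> PoseSeries:
    """Spin the moving capsomer about its own center after a standoff.

    The spin axis is the plane normal through the (displaced) moving center of
    mass, so the center of mass is identical across the series.
    """
    if standoff < 0:
        raise ValueError("standoff must be >= 0")
    com_m = pair.moving.center_of_mass
    shift = standoff * pair.native_axis
    poses = [
        Pose(rotation_about_axis(pair.plane_normal, a), shift, com_m, float(a), "spin")
        for a in _grid(start, stop, step)
    ]
    return PoseSeries(pair, poses, (start, stop, step), "spin")


def rotate_around(pair: CapsomerPair, start: float, stop: float, step: float,
                  standoff: float = 20.0) -> PoseSeries:
    """Orbit the moving capsomer about the fixed one (position and orientation
    co-rotate as a single rigid rotation about the plane normal through the
    fixed center of mass), after a standoff along the native axis.
    """
    if standoff < 0:
        raise ValueError("standoff must be >= 0")
    com_f = pair.fixed.center_of_mass
    shift = standoff * pair.native_axis
    poses = []
    for a in _grid(start, stop, step):
        R = rotation_about_axis(pair.plane_normal, a)
        poses.append(Pose(R, R @ shift, com_f, float(a), "rotate_around"))
    return PoseSeries(pair, poses, (start, stop, step), "rotate_around")


def export_series(series: PoseSeries, out_dir) -> None:
    """Write one PDB per pose plus a TSV manifest.

    Files are named ``<operation>_<scan_param>.pdb``; the manifest lists pose
    index, operation, scan parameter and the center-of-mass separation
    recomputed from the transformed coordinates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    com_f = series.pair.fixed.center_of_mass
    rows = []
    for i, (pose, moved) in enumerate(zip(series.poses, series.moving_models())):
        name = f"{pose.operation}_{pose.scan_param:+09.3f}.pdb"
        structure_io.write_pdb(moved, out / name)
        sep = float(np.linalg.norm(moved.center_of_mass - com_f))
        rows.append((i, pose.operation, pose.scan_param, sep))
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("index\top\tparam\tcom_sep_A\n")
        for i, op, p, sep in rows:
            fh.write(f"{i}\t{op}\t{p:.6g}\t{sep:.6f}\n")
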