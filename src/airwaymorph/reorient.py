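"""Rigid reorientation to the Frankfort-horizontal / midsagittal reference frame.

The anatomical reference frame is built in two sequential steps, mirroring
clinical practice: first the head is levelled so the Frankfort horizontal
plane (through right porion and both orbitale points) becomes the
horizontal z = const plane, then a rotation about the vertical axis brings
the midsagittal plane (through nasion, anterior nasal spine and the
mid-posterior foramen magnum point) to the x–z plane.  The second rotation
is purely about z, so it cannot undo the first alignment.  Conventions:
+X anterior (foramen magnum → nasion), +Y subject-left, +Z superior
(the side of the orbits on which sella lies), origin at sella.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .landmarks import RAW, REORIENTED, LandmarkSet

FH_LANDMARKS = ("rPo", "rOr", "lOr")
MIDSAGITTAL_LANDMARKS = ("Na", "ANS", "MGNM")


class DegenerateGeometryError(ValueError):
    """Landmark configuration too degenerate to define the reference planes."""


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``normal·x = offset`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def signed_distance(self, p) -> float:
        return float(np.dot(self.normal, np.asarray(p, dtype=float)) - self.offset)


def fit_plane(p1, p2, p3) -> Plane:
    """Plane through three points; normal by right-hand rule on (p2−p1, p3−p1).

    Raises :class:`DegenerateGeometryError` when the triangle area is below
    1e-6 mm² (collinear or coincident points).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(n)
    if area <= 1e-6:
        raise DegenerateGeometryError(
            f"points are collinear (triangle area {area:.2e} mm^2)")
    n = n / np.linalg.norm(n)
    return Plane(normal=n, offset=float(np.dot(n, p1)))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``x ↦ R x + t`` (rotation + translation, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "convention": "+X anterior, +Y subject-left, +Z superior, origin at S",
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:  # antiparallel: rotate pi about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def compute_reorientation(landmarks: LandmarkSet) -> RigidTransform:
    """Rigid transform aligning a subject to the FH + midsagittal reference frame.

    After the transform, rPo/rOr/lOr share one z value, the horizontal
    component of the midsagittal normal lies along ±Y, the origin is at S,
    and +X points from MGNM toward Na.
    """
    landmarks.require(FH_LANDMARKS + MIDSAGITTAL_LANDMARKS + ("S",))

    fh = fit_plane(*(landmarks[n] for n in FH_LANDMARKS))
    # orient FH normal toward sella's side (superior)
    n_fh = fh.normal if fh.signed_distance(landmarks["S"]) >= 0 else -fh.normal

    ms = fit_plane(*(landmarks[n] for n in MIDSAGITTAL_LANDMARKS))
    angle = np.degrees(np.arccos(np.clip(abs(np.dot(n_fh, ms.normal)), 0, 1)))
    if angle < 10.0:
        raise DegenerateGeometryError(
            f"FH and midsagittal planes nearly parallel ({angle:.1f} deg apart)")

    R1 = _rotation_between(n_fh, np.array([0.0, 0.0, 1.0]))

    # in-plane rotation: align horizontal part of the midsagittal normal to Y
    m = R1 @ ms.normal
    mh = np.array([m[0], m[1]])
    if np.linalg.norm(mh) < 1e-9:
        raise DegenerateGeometryError("midsagittal normal vertical after FH alignment")
    theta = np.arctan2(mh[0], mh[1])  # rotates (sin, cos)-style onto +Y
    c, s = np.cos(theta), np.sin(theta)
    R2 = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    R = R2 @ R1

    # resolve the +-Y ambiguity: +X must point from MGNM toward Na (anterior)
    if (R @ (landmarks["Na"] - landmarks["MGNM"]))[0] < 0:
        R = np.diag([-1.0, -1.0, 1.0]) @ R  # extra pi turn about z
    return RigidTransform(R, -R @ landmarks["S"])


def midsagittal_residual(landmarks: LandmarkSet) -> float:
    """QC metric: max |y| of the midsagittal landmarks in a reoriented set."""
    return float(max(abs(landmarks[n][1]) for n in MIDSAGITTAL_LANDMARKS))


def apply_transform(obj, t: RigidTransform):
    """Apply a rigid transform to a :class:`LandmarkSet` or a ``VoxelGrid``.

    Landmarks are mapped exactly; binary grids are resampled onto an
    axis-aligned grid of the same voxel size by nearest neighbour, which
    preserves binarity (a small volume change from resampling is expected).
    """
    from .airway import VoxelGrid  # local import to avoid a cycle

    if isinstance(obj, LandmarkSet):
        pts = {n: t(p) for n, p in obj.points.items()}
        return obj.replace(points=pts, frame=REORIENTED)
    if isinstance(obj, VoxelGrid):
        return _transform_grid(obj, t)
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")


def _transform_grid(grid, t: RigidTransform):
    from .airway import VoxelGrid

    v = grid.voxel_mm
    # world-space corners of the input grid -> output bounding box
    shape = np.array(grid.data.shape)
    corners_idx = np.array([[i, j, k] for i in (0, shape[0] - 1)
                            for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)])
    corners = t(grid.origin_mm + corners_idx * v)
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    out_shape = np.maximum(np.round((hi - lo) / v).astype(int) + 1, 1)

    # map output voxel centers back through t^-1 into input index space
    inv = t.inverse()
    # world_out = lo + idx*v ; world_in = R^T (world_out - t.t) ; idx_in = (world_in - origin)/v
    A = inv.rotation  # index-space linear map is the same rotation (isotropic voxels)
    offset_world = inv(lo)
    offset_idx = (offset_world - grid.origin_mm) / v
    data = ndimage.affine_transform(
        grid.data.astype(np.uint8), A, offset=offset_idx,
        output_shape=tuple(out_shape), order=0, mode="constant", cval=0)
    return VoxelGrid(data=data.astype(np.uint8), voxel_mm=v, origin_mm=lo,
                     frame=REORIENTED)
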