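"""Pinhole C-arm projection geometry.

World frame convention (fixed for the whole package):

* the X-ray **source** sits at the origin ``(0, 0, 0)``;
* ``x`` is the source-to-detector (patient anterior-posterior) axis;
* ``y`` is the patient mediolateral (ML) axis;
* ``z`` is the patient superior-inferior (SI) axis;
* the **detector plane** is ``x = SDD`` with its normal along ``x``;
* the **isocenter** is the midpoint ``(SDD/2, 0, 0)``; at the nominal pose
  the CT volume is placed with its center on the isocenter and its anterior
  face toward the source.

Detector pixel coordinates ``(u, v)`` are 0-based with pixel centers at
integer coordinates; ``u`` increases with ``+y`` and ``v`` with ``+z`` at
the nominal pose.  The principal point (center of projection, COP) defaults
to the detector center.

A 6-DOF pose ``(Tx, Ty, Tz, Rx, Ry, Rz)`` moves the C-arm (the rigid
source+detector pair) relative to the fixed volume: the rig is rotated by
``R = Rz @ Ry @ Rx`` (degrees, fixed order, about the world axes centered at
the isocenter) and then translated by ``(Tx, Ty, Tz)`` in mm.  The nominal
pose is the all-zeros vector.  Equivalently, a world point ``p`` seen by the
moved camera has camera-frame coordinates

    p_cam = R.T @ (p - ic - t) + ic

with ``ic`` the isocenter.  All distances are mm, all angles degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CArmIntrinsics",
    "CArmPose",
    "ProjectionMatrix",
    "LandmarkSet",
    "NominalGeometry",
    "nominal_geometry",
    "rotation_matrix",
    "build_projection",
    "project_points",
    "GeometryError",
]


class GeometryError(ValueError):
    """Invalid projection geometry (bad intrinsics, degenerate pose, ...)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CArmIntrinsics:
    """Fixed internal geometry of the modeled C-arm.

    Parameters
    ----------
    sdd:
        Source-to-detector distance (focal length) in mm.
    pixel_size:
        Detector pixel pitch ``(Px, Py)`` in mm/px.
    detector_size:
        Detector dimensions ``(nu, nv)`` in pixels.
    cop:
        Principal point ``(u0, v0)`` in pixel coordinates.  Defaults to the
        detector center ``((nu-1)/2, (nv-1)/2)``.
    """

    sdd: float
    pixel_size: tuple[float, float]
    detector_size: tuple[int, int]
    cop: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sdd) and self.sdd > 0):
            raise GeometryError(f"sdd must be positive and finite, got {self.sdd}")
        px, py = self.pixel_size
        if not (px > 0 and py > 0 and np.isfinite(px) and np.isfinite(py)):
            raise GeometryError(f"pixel_size must be positive, got {self.pixel_size}")
        nu, nv = self.detector_size
        if not (nu >= 1 and nv >= 1):
            raise GeometryError(f"detector_size must be >= 1, got {self.detector_size}")
        if self.cop is None:
            object.__setattr__(self, "cop", ((nu - 1) / 2.0, (nv - 1) / 2.0))
        u0, v0 = self.cop  # type: ignore[misc]
        if not (-0.5 <= u0 <= nu - 0.5 and -0.5 <= v0 <= nv - 0.5):
            raise GeometryError(f"cop {self.cop} outside detector bounds {self.detector_size}")

    @property
    def isocenter(self) -> np.ndarray:
        """Isocenter ``(SDD/2, 0, 0)`` in world mm."""
        return np.array([self.sdd / 2.0, 0.0, 0.0])

    @property
    def detector_extent_mm(self) -> tuple[float, float]:
        """Physical detector size ``(nu*Px, nv*Py)`` in mm."""
        return (self.detector_size[0] * self.pixel_size[0],
                self.detector_size[1] * self.pixel_size[1])


@dataclass(frozen=True)
class CArmPose:
    """6-DOF extrinsic pose of the C-arm: translations mm, rotations degrees."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = (*self.translation, *self.rotation)
        if not all(math.isfinite(v) for v in vals):
            raise GeometryError(f"pose components must be finite, got {vals}")

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "CArmPose":
        """Build from a 6-vector ``(Tx, Ty, Tz, Rx, Ry, Rz)``."""
        x = tuple(float(v) for v in x)
        if len(x) != 6:
            raise GeometryError(f"pose vector must have 6 components, got {len(x)}")
        return cls(translation=x[:3], rotation=x[3:])

    def as_vector(self) -> np.ndarray:
        return np.array([*self.translation, *self.rotation], dtype=float)

    @property
    def is_nominal(self) -> bool:
        return not np.any(self.as_vector())


@dataclass(frozen=True)
class ProjectionMatrix:
    """3x4 homogeneous projection matrix, intrinsic times extrinsic."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4):
            raise GeometryError(f"projection matrix must be 3x4, got {m.shape}")
        if np.linalg.matrix_rank(m) != 3:
            raise GeometryError("projection matrix must have rank 3")
        object.__setattr__(self, "matrix", m)


@dataclass
class LandmarkSet:
    """Labeled vertebral centroids, 3D (mm, world or volume frame) or 2D (px).

    Labels are vertebral level names (``T5`` ... ``L4``); correspondence
    between sets is always by label, order is preserved.
    """

    labels: list[str]
    coords: np.ndarray  # (N, 3) mm or (N, 2) px

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if len(self.labels) == 0:
            self.coords = self.coords.reshape(0, self.coords.shape[-1] or 3)
        if self.coords.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels but {self.coords.shape[0]} coordinate rows")
        if len(self.labels) and self.coords.shape[1] not in (2, 3):
            raise ValueError(f"coords must be (N,2) or (N,3), got {self.coords.shape}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate landmark labels in {self.labels}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def get(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "LandmarkSet":
        idx = [self.labels.index(l) for l in labels]
        return LandmarkSet([self.labels[i] for i in idx], self.coords[idx])

    def translated(self, offset: Sequence[float]) -> "LandmarkSet":
        return LandmarkSet(list(self.labels), self.coords + np.asarray(offset, float))

    def sorted_by_level(self) -> "LandmarkSet":
        return self.subset(sorted(self.labels, key=level_sort_key))


def level_sort_key(label: str) -> tuple[int, float, str]:
    """Sort key placing vertebral levels in anatomical superior->inferior
    order: C1..C7 < T1..T12 < L1..L5 < S...; unknown labels sort last,
    alphabetically."""
    groups = {"C": 0, "T": 1, "L": 2, "S": 3}
    if label and label[0].upper() in groups:
        try:
            return (groups[label[0].upper()], float(label[1:]), "")
        except ValueError:
            pass
    return (9, 0.0, label)


@dataclass(frozen=True)
class NominalGeometry:
    """World-frame description of the imaging rig at the all-zero pose."""

    source: np.ndarray          # (3,) mm
    isocenter: np.ndarray       # (3,) mm
    detector_plane_x: float     # mm; plane x = SDD, normal along +x
    detector_normal: np.ndarray


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def nominal_geometry(intrinsics: CArmIntrinsics) -> NominalGeometry:
    """World-frame rig layout at the nominal pose.

    Source at the origin, isocenter at ``(SDD/2, 0, 0)``, detector plane at
    ``x = SDD`` with normal along ``x``.  The CT volume center is placed at
    the isocenter with the anterior face toward the source (the volume
    occupies the region around the isocenter between source and detector).
    """
    return NominalGeometry(
        source=np.zeros(3),
        isocenter=intrinsics.isocenter,
        detector_plane_x=float(intrinsics.sdd),
        detector_normal=np.array([1.0, 0.0, 0.0]),
    )


def rotation_matrix(rotation_deg: Sequence[float]) -> np.ndarray:
    """Rotation ``R = Rz @ Ry @ Rx`` for Euler angles in degrees.

    Fixed-order rotations about the world axes; the order is a package
    convention (documented in the module docstring) applied consistently in
    simulation and recovery.
    """
    rx, ry, rz = np.deg2rad(np.asarray(rotation_deg, dtype=float))
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def camera_frame(intrinsics: CArmIntrinsics, pose: CArmPose) -> tuple[np.ndarray, np.ndarray]:
    """Source position and rotation of the moved rig, world frame.

    Returns ``(source_world, R)`` where a rig point at nominal position ``q``
    moves to ``R @ (q - ic) + ic + t``.
    """
    ic = intrinsics.isocenter
    t = np.asarray(pose.translation, dtype=float)
    R = rotation_matrix(pose.rotation)
    return R @ (-ic) + ic + t, R


def build_projection(intrinsics: CArmIntrinsics, pose: CArmPose) -> ProjectionMatrix:
    """3x4 projection matrix: homogeneous ``(u*w, v*w, w) = P @ (x, y, z, 1)``.

    ``w`` is the camera-frame depth along the source-to-detector axis, so
    ``w <= 0`` marks points at or behind the source plane.  At the nominal
    pose the extrinsic factor is the identity placement of
    :func:`nominal_geometry`.
    """
    u0, v0 = intrinsics.cop  # type: ignore[misc]
    px, py = intrinsics.pixel_size
    sdd = intrinsics.sdd
    # intrinsic: u = u0 + (SDD * y_cam / x_cam) / Px, v likewise with z.
    K = np.array([
        [u0, sdd / px, 0.0],
        [v0, 0.0, sdd / py],
        [1.0, 0.0, 0.0],
    ])
    ic = intrinsics.isocenter
    t = np.asarray(pose.translation, dtype=float)
    R = rotation_matrix(pose.rotation)
    # p_cam = R.T @ (p - ic - t) + ic
    E = np.hstack([R.T, (ic - R.T @ (ic + t)).reshape(3, 1)])
    return ProjectionMatrix(K @ E)


def project_points(matrix: ProjectionMatrix, points3d: LandmarkSet) -> LandmarkSet:
    """Project labeled 3D world points to detector pixels ``(u, v)``.

    Labels and order are preserved.  Raises :class:`GeometryError` if any
    point is at or behind the source plane (homogeneous depth <= 0).
    """
    if points3d.dim != 3 and len(points3d):
        raise GeometryError("project_points expects 3D landmarks")
    uv, depth = project_array(matrix, points3d.coords.reshape(-1, 3))
    bad = depth <= 0
    if np.any(bad):
        names = [points3d.labels[i] for i in np.nonzero(bad)[0]]
        raise GeometryError(f"points at or behind the source plane: {names}")
    return LandmarkSet(list(points3d.labels), uv)


def project_array(matrix: ProjectionMatrix, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized projection of an ``(N, 3)`` array.

    Returns ``(uv, depth)``; rows with ``depth <= 0`` hold non-normalized
    garbage and must be handled by the caller (no exception raised here, the
    optimizer needs a non-throwing path).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    h = matrix.matrix @ np.hstack([pts, np.ones((len(pts), 1))]).T  # (3, N)
    depth = h[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        uv = (h[:2] / depth).T
    return uv, depth
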