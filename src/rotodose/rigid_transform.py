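"""Isocenter-centered rigid transforms for setup-error simulation.

A systematic rotational setup error is modelled as a rigid transform of
the patient about the treatment isocenter: a composed rotation
``M = Rpitch @ Rroll @ Ryaw`` (pitch about x-lateral, roll about
y-longitudinal, yaw about z-vertical, right-hand rule, extrinsic room
axes) plus a residual translation ``T``.  Points map as::

    p' = M @ (p - isocenter) + isocenter + T

All angles are in degrees, all lengths in mm.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid

__all__ = [
    "RigidTransform",
    "rotation_matrix",
    "euler_angles",
    "apply_to_points",
    "resample_volume",
    "transform_structure",
]


def _elementary(axis: int, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a coordinate axis (column-vector convention)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


def rotation_matrix(pitch: float, roll: float, yaw: float) -> np.ndarray:
    """Composed rotation matrix ``Rpitch @ Rroll @ Ryaw``.

    Parameters are angles in degrees about the x (pitch), y (roll) and z
    (yaw) room axes; magnitudes must not exceed 180 degrees.
    """
    angles = np.array([pitch, roll, yaw], dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError(f"rotation angles must be finite, got {angles}")
    if np.any(np.abs(angles) > 180.0):
        raise ValueError(f"rotation angle magnitudes must be <= 180 deg, got {angles}")
    return _elementary(0, pitch) @ _elementary(1, roll) @ _elementary(2, yaw)


def euler_angles(matrix: np.ndarray) -> tuple[float, float, float]:
    """Factor a rotation matrix back into (pitch, roll, yaw) degrees.

    Inverse of :func:`rotation_matrix` for |roll| < 90 deg; the
    gimbal-adjacent regime is far outside the +-7 deg operating range of
    the setup-error study and is rejected.
    """
    m = np.asarray(matrix, dtype=float)
    sr = np.clip(m[0, 2], -1.0, 1.0)
    if abs(sr) > 0.999999:
        raise ValueError("roll within ~0.08 deg of +-90 deg: outside supported range")
    roll = np.arcsin(sr)
    yaw = np.arctan2(-m[0, 1], m[0, 0])
    pitch = np.arctan2(-m[1, 2], m[2, 2])
    return tuple(np.rad2deg([pitch, roll, yaw]))  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Rigid transform about a fixed isocenter.

    Attributes
    ----------
    pitch, roll, yaw:
        Rotation angles in degrees about x/y/z room axes.
    rotation:
        The composed 3x3 matrix ``Rpitch @ Rroll @ Ryaw`` (orthonormal,
        det +1).
    translation:
        Residual translation in mm, applied after the rotation.
    isocenter:
        Rotation center in room coordinates (mm).
    """

    pitch: float
    roll: float
    yaw: float
    translation: np.ndarray
    isocenter: np.ndarray
    rotation: np.ndarray = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "isocenter", np.asarray(self.isocenter, dtype=float))
        if self.rotation is None:
            object.__setattr__(self, "rotation",
                               rotation_matrix(self.pitch, self.roll, self.yaw))
        else:
            object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-10):
            raise ValueError("rotation matrix must have determinant +1")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_angles(cls, pitch: float, roll: float, yaw: float,
                    translation=(0.0, 0.0, 0.0),
                    isocenter=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(float(pitch), float(roll), float(yaw),
                   np.asarray(translation, dtype=float),
                   np.asarray(isocenter, dtype=float))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, translation, isocenter) -> "RigidTransform":
        pitch, roll, yaw = euler_angles(matrix)
        return cls(pitch, roll, yaw, np.asarray(translation, dtype=float),
                   np.asarray(isocenter, dtype=float),
                   rotation=np.asarray(matrix, dtype=float))

    @classmethod
    def identity(cls, isocenter=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls.from_angles(0.0, 0.0, 0.0, isocenter=isocenter)

    # -- algebra ------------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map room-coordinate points (mm): R (p - iso) + iso + T."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[-1] != 3 or not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite 3-vectors (mm)")
        out = (pts - self.isocenter) @ self.rotation.T + self.isocenter + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform.from_matrix(rinv, -(rinv @ self.translation), self.isocenter)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        if not np.allclose(self.isocenter, other.isocenter, atol=1e-9):
            raise ValueError("cannot compose transforms with different isocenters")
        m = self.rotation @ other.rotation
        t = self.rotation @ other.translation + self.translation
        return RigidTransform.from_matrix(m, t, self.isocenter)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw], dtype=float)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=atol)
                and np.allclose(self.translation, 0.0, atol=atol))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pitch_deg": self.pitch,
            "roll_deg": self.roll,
            "yaw_deg": self.yaw,
            "translation_mm": self.translation.tolist(),
            "isocenter_mm": self.isocenter.tolist(),
            "rotation_matrix": self.rotation.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        t = cls.from_angles(d["pitch_deg"], d["roll_deg"], d["yaw_deg"],
                            d["translation_mm"], d["isocenter_mm"])
        if "rotation_matrix" in d and not np.allclose(
                t.rotation, np.asarray(d["rotation_matrix"]), atol=1e-8):
            raise ValueError("stored rotation matrix disagrees with stored angles")
        return t

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def apply_to_points(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(points)


_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def resample_volume(v: VolumeGrid, t: RigidTransform,
                    interpolation: str = "trilinear",
                    background: float = 0.0) -> VolumeGrid:
    """Apply a rigid transform to a volume, resampled on its own lattice.

    The volume is moved *forward* by ``t`` (a feature at p appears at
    t(p)); the implementation pulls values through the inverse mapping so
    the output grid geometry equals the input's.  Out-of-field voxels get
    ``background`` (use the CT air value for images, 0 for structures and
    dose).
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP_ORDER)}")
    # source index = S^-1 Rinv S i_out + S^-1 (Rinv (o - c - T) + c - o)
    s = v.spacing
    rinv = t.rotation.T
    mat = (rinv * s[np.newaxis, :]) / s[:, np.newaxis]
    off = (rinv @ (v.origin - t.isocenter - t.translation) + t.isocenter - v.origin) / s
    out = ndimage.affine_transform(
        v.values.astype(float, copy=False), mat, offset=off,
        order=_INTERP_ORDER[interpolation], mode="constant", cval=background,
    )
    return VolumeGrid(out, v.spacing.copy(), v.origin.copy(), v.axis_labels)


def transform_structure(s, t: RigidTransform, clip_warn_fraction: float = 1e-2):
    """Transport a fractional-occupancy structure through a rigid transform.

    Occupancy is interpolated trilinearly (never re-binarized), which is
    what keeps structure volumes stable at the sub-percent level.  If
    more than ``clip_warn_fraction`` of the occupancy mass is lost (the
    structure carried outside the grid bounds), a warning reports the
    lost fraction.
    """
    from .structures import Structure  # local import to avoid a cycle

    grid = VolumeGrid(s.occupancy, s.spacing, s.origin)
    moved = resample_volume(grid, t, interpolation="trilinear", background=0.0)
    occ = np.clip(moved.values, 0.0, 1.0)
    before = float(np.sum(s.occupancy))
    after = float(np.sum(occ))
    if before > 0:
        clipped = max(0.0, (before - after) / before)
        if clipped > clip_warn_fraction:
            warnings.warn(
                f"structure '{s.name}': {100 * clipped:.3f}% of occupancy mass lost "
                "under the transform (grid-boundary clipping)",
                stacklevel=2,
            )
    return Structure(name=s.name, role=s.role, shape_class=s.shape_class,
                     occupancy=occ.astype(np.float32), spacing=s.spacing.copy(),
                     origin=s.origin.copy())
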