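"""Volumetric scalar grids in room coordinates.

A :class:`VolumeGrid` holds a 3D scalar field (HU-like intensities for
CT-style images, Gy for dose grids, fractional occupancy for structures)
on a regular, axis-aligned lattice.  Array axes follow IEC 61217-style
patient axes: axis 0 is x (lateral, left-right), axis 1 is y
(longitudinal, inferior-superior), axis 2 is z (vertical,
posterior-anterior).  The mapping from a 0-based voxel index ``i`` to a
room coordinate in mm uses the voxel-center convention::

    p = origin + i * spacing
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

AXIS_LABELS = ("x-lateral", "y-longitudinal", "z-vertical")


@dataclasses.dataclass
class VolumeGrid:
    """A 3D scalar field with spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be 3-vectors")
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def physical_center(self) -> np.ndarray:
        """Room coordinate of the grid center (mm)."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    def index_to_room(self, indices: np.ndarray) -> np.ndarray:
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + indices * self.spacing

    def room_to_index(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.origin) / self.spacing

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis room coordinates of voxel centers (open mesh)."""
        axes = [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)]
        return np.meshgrid(*axes, indexing="ij", sparse=True)  # type: ignore[return-value]

    # -- sampling -----------------------------------------------------------

    def sample(self, points: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the field at room-coordinate points (mm).

        ``order=1`` is trilinear, ``order=0`` nearest-neighbour.  Points
        outside the grid return ``cval``.
        """
        idx = self.room_to_index(points)
        return ndimage.map_coordinates(
            self.values.astype(float, copy=False), idx.T, order=order,
            mode="constant", cval=cval,
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside the grid extent."""
        idx = self.room_to_index(points)
        upper = np.array(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.spacing.copy(), self.origin.copy(),
                          self.axis_labels)

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    # -- I/O ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as NIfTI (.nii/.nii.gz) or NRRD (.nrrd), by extension."""
        path = Path(path)
        if path.suffix == ".nrrd":
            import SimpleITK as sitk

            sitk.WriteImage(self.to_sitk(), str(path))
        else:
            affine = np.eye(4)
            affine[:3, :3] = np.diag(self.spacing)
            affine[:3, 3] = self.origin
            nib.save(nib.Nifti1Image(np.asarray(self.values), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeGrid":
        path = Path(path)
        if path.suffix == ".nrrd":
            import SimpleITK as sitk

            return cls.from_sitk(sitk.ReadImage(str(path)))
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.diag(affine[:3, :3]).copy()
        return cls(np.asarray(img.dataobj), spacing, affine[:3, 3].copy())

    def to_sitk(self):
        """Convert to a SimpleITK image (axis order reversed to z,y,x)."""
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.transpose(self.values, (2, 1, 0)).astype(np.float32)))
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        return img

    @classmethod
    def from_sitk(cls, img) -> "VolumeGrid":
        import SimpleITK as sitk

        values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return cls(values, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
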