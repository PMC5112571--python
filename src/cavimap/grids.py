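"""3-D scalar fields on a regular voxel grid.

A :class:`VolumeGrid` couples a voxel array with the affine mapping voxel
indices to world millimetres, mirroring the NIfTI convention used by
``nibabel``.  Every map in the pipeline (T1-weighted volumes, T1 maps,
gadolinium-concentration maps, masks, labels) is carried in this container,
and voxelwise arithmetic between two volumes first checks that they live on
the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import IncompatibleGridsError

__all__ = ["VolumeGrid"]

_AFFINE_ATOL = 1e-4  # mm; grids closer than this are "the same"


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel spacing and a voxel-to-world affine.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar values, one per voxel.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> world-mm transform (NIfTI style).
    units : str
        Free-text unit label (``"ms"``, ``"mM"``, ``"a.u."``, ``"label"``).
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.voxels.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 else out

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        out = xyz @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if out.shape[0] == 1 else out

    # -- compatibility ----------------------------------------------------
    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_AFFINE_ATOL
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "operand") -> None:
        if not self.same_grid(other):
            raise IncompatibleGridsError(
                f"{what}: shapes {self.shape} vs {other.shape} or affines differ"
            )

    def with_voxels(self, voxels: np.ndarray, units: str | None = None) -> "VolumeGrid":
        """A new volume on this grid (shape must match)."""
        voxels = np.asarray(voxels)
        if voxels.shape != self.shape:
            raise IncompatibleGridsError(
                f"replacement voxels {voxels.shape} != grid {self.shape}"
            )
        return VolumeGrid(voxels, self.affine.copy(), self.units if units is None else units)

    # -- I/O ---------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, units: str = "a.u.") -> "VolumeGrid":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        return cls(data, np.asarray(img.affine), units)
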