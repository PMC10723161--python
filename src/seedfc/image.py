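"""Core in-memory image container and grid geometry helpers.

A :class:`Bold4D` couples a 4D BOLD intensity array with the affine mapping
voxel indices to MNI millimetre coordinates and the repetition time (TR).
All pipeline stages accept and return this container so that grid geometry
and sampling rate travel with the data.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class Bold4D:
    """A 4D voxel time-series image.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n_volumes)
        BOLD intensities.
    affine : ndarray, shape (4, 4)
        Voxel index -> MNI mm mapping (NIfTI convention).
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.n_volumes < 2:
            raise ValueError("a BOLD series needs at least 2 volumes")
        if not float(self.tr) > 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "Bold4D":
        """A copy sharing geometry and TR but holding new intensities."""
        return replace(self, data=data)


def voxel_to_mni(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to MNI mm coordinates."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def mni_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map MNI mm coordinates (..., 3) to (fractional) voxel indices."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(affine[:3, :3])
    return (xyz - affine[:3, 3]) @ inv.T


def voxel_center_grid_mm(affine: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """MNI mm coordinates of every voxel center, shape (*shape, 3)."""
    ijk = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    )
    return voxel_to_mni(affine, ijk)
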