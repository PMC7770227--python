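"""Voxel-grid metadata shared by all volumetric containers.

Every map in the pipeline lives on a common isotropic voxel grid in a
standard space; the grid is the minimal piece of geometry needed to
convert between voxel indices and millimetres and to build NIfTI affines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """An isotropic 3-D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis, ``(nx, ny, nz)``.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """RAS affine with the voxel size on the diagonal, origin at voxel (0,0,0)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def voxel_to_mm(self, ijk) -> np.ndarray:
        return np.asarray(ijk, dtype=float) * self.voxel_size_mm

    def mm_to_voxel(self, xyz) -> np.ndarray:
        return np.asarray(xyz, dtype=float) / self.voxel_size_mm

    def check_data(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data)
        if data.shape != self.shape:
            raise ValueError(f"map shape {data.shape} does not match grid {self.shape}")
        return data


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Convert a Gaussian FWHM in mm to a kernel standard deviation in voxels."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
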