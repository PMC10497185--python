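"""Rectilinear voxel grids with an affine world (MNI, mm) mapping.

Everything spatial in this package — simulated volumes, t-maps, spherical
masks — lives on a :class:`VolumeGrid`: an axis-aligned grid of isotropic or
anisotropic voxels whose world coordinates are given by an invertible affine.
Voxel indices are 0-based; world coordinates follow the MNI convention
(x: left→right, y: posterior→anterior, z: inferior→superior), in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import InvalidConfigError


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid embedded in world (mm) space.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z.
    voxel_size_mm
        Voxel edge lengths in mm (all positive).
    origin_mm
        World coordinate of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int] = (40, 48, 38)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (-57.0, -63.0, -39.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise InvalidConfigError(f"grid shape must be positive, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidConfigError(
                f"voxel size must be positive, got {self.voxel_size_mm}"
            )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index → world-mm affine (diagonal scaling + origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world-mm coordinates of voxel centres."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_mm)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm coordinates to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)


def default_grid() -> VolumeGrid:
    """The package's desk-scale analysis grid.

    40 x 48 x 38 voxels at 3 mm isotropic, origin placed so that 10 mm
    spheres around all six default ROI centres fit inside with margin.
    """
    return VolumeGrid()
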