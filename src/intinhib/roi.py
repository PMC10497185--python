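"""Spherical regions of interest and multi-voxel pattern extraction.

The analysis restricts pattern similarity to six a-priori regions of the
motor action-release/inhibition network: right pre-supplementary motor area
(preSMA), right inferior frontal gyrus (IFG), bilateral insula, left caudate
nucleus and left primary motor cortex (M1).  Each region is a 10 mm sphere
around a peak MNI coordinate, rasterised onto the analysis grid by including
every voxel whose centre lies within the radius (boundary inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .conditions import CONDITIONS
from .grid import VolumeGrid

log = logging.getLogger(__name__)


class EmptyMaskError(ValueError):
    """Sphere does not cover any voxel centre of the grid."""


@dataclass(frozen=True)
class ROISpec:
    """A spherical region of interest in MNI world coordinates."""

    name: str
    center_mni_mm: tuple[float, float, float]
    radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"radius must be positive, got {self.radius_mm}")


#: The six pre-registered ROI spheres (10 mm radius around univariate peaks).
DEFAULT_ROIS: tuple[ROISpec, ...] = (
    ROISpec("preSMA", (4.0, 18.0, 48.0)),
    ROISpec("IFG", (40.0, 40.0, 6.0)),
    ROISpec("insula_R", (34.0, 22.0, 4.0)),
    ROISpec("insula_L", (-34.0, 20.0, 4.0)),
    ROISpec("caudate", (-12.0, 18.0, -2.0)),
    ROISpec("M1", (-34.0, -22.0, 56.0)),
)


def make_sphere_mask(spec: ROISpec, grid: VolumeGrid) -> np.ndarray:
    """Boolean mask of voxels whose centre is within ``radius_mm`` of the
    sphere centre (Euclidean distance in world mm, boundary inclusive).

    Raises
    ------
    EmptyMaskError
        If no voxel centre falls inside the sphere.
    """
    centers = grid.voxel_centers()
    d2 = np.sum((centers - np.asarray(spec.center_mni_mm)) ** 2, axis=-1)
    mask = d2 <= spec.radius_mm**2 + 1e-9
    if not mask.any():
        raise EmptyMaskError(
            f"ROI {spec.name!r} at {spec.center_mni_mm} (r={spec.radius_mm} mm) "
            f"covers no voxel centre of grid shape {grid.shape}"
        )
    return mask


def extract_patterns(tmaps: dict[str, np.ndarray] | list[np.ndarray],
                     mask: np.ndarray) -> np.ndarray:
    """Extract the 4 x V in-mask pattern matrix from the four t-maps.

    Rows follow the fixed condition order (Go, NoGo, ChooseGo, ChooseNoGo).
    Voxels that are non-finite in *any* map are dropped from *all* rows
    (listwise deletion; the count is logged).

    Parameters
    ----------
    tmaps
        Either a dict keyed by condition name or a list of four arrays in
        the canonical order; every array must match the mask's shape.
    mask
        Boolean array selecting in-ROI voxels.

    Returns
    -------
    ndarray of shape (4, n_surviving_voxels)

    Raises
    ------
    ValueError
        On shape mismatch or when fewer than 2 voxels survive cleaning.
    """
    if isinstance(tmaps, dict):
        missing = [c for c in CONDITIONS if c not in tmaps]
        if missing:
            raise ValueError(f"missing t-maps for conditions: {missing}")
        maps = [np.asarray(tmaps[c]) for c in CONDITIONS]
    else:
        maps = [np.asarray(m) for m in tmaps]
        if len(maps) != len(CONDITIONS):
            raise ValueError(f"expected {len(CONDITIONS)} t-maps, got {len(maps)}")
    mask = np.asarray(mask, dtype=bool)
    for m in maps:
        if m.shape != mask.shape:
            raise ValueError(
                f"t-map shape {m.shape} does not match mask shape {mask.shape}"
            )
    pat = np.stack([m[mask] for m in maps], axis=0)
    finite = np.isfinite(pat).all(axis=0)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.warning("extract_patterns: dropped %d non-finite voxel(s)", n_dropped)
    pat = pat[:, finite]
    if pat.shape[1] < 2:
        raise ValueError(
            f"fewer than 2 finite in-mask voxels survive ({pat.shape[1]})"
        )
    return pat
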