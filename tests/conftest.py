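"""Shared fixtures: desk-scale grids, masks and sessions.

Tests run the identical machinery as a full-scale analysis on a smaller
design (fewer trials and volumes, a grid cropped to one ROI sphere) so the
whole pipeline stays fast.
"""

import numpy as np
import pytest

from intinhib.grid import VolumeGrid
from intinhib.roi import ROISpec, make_sphere_mask
from intinhib.synthetic import BehaviourRates, build_session

#: Scaled-down per-run trial counts (same 50/17/33 mix as the full task).
SMALL_TRIALS = {"Go": 36, "NoGo": 12, "Choose": 24}
SMALL_VOLUMES = 72


@pytest.fixture(scope="session")
def sphere_grid() -> VolumeGrid:
    """A 9^3 grid of 3 mm voxels centred on the preSMA peak coordinate."""
    return VolumeGrid(shape=(9, 9, 9), voxel_size_mm=(3, 3, 3),
                      origin_mm=(4 - 12, 18 - 12, 48 - 12))


@pytest.fixture(scope="session")
def presma_spec() -> ROISpec:
    return ROISpec("preSMA", (4.0, 18.0, 48.0), 10.0)


@pytest.fixture(scope="session")
def presma_mask(presma_spec, sphere_grid) -> np.ndarray:
    return make_sphere_mask(presma_spec, sphere_grid)


@pytest.fixture(scope="session")
def small_session():
    """A 3-run scaled session with no omissions or commission errors."""
    rates = BehaviourRates(p_choose_go=0.5, p_nogo_error=0.0, p_go_omission=0.0)
    return build_session(seed=11, rates=rates, trials_per_run=SMALL_TRIALS,
                        n_volumes=SMALL_VOLUMES)
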