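"""Fisher-z representational similarity over ROI t-map patterns.

For each subject and ROI, the spatial t-statistic patterns of the four
analysed conditions are correlated pairwise across voxels (Pearson), the
correlations are Fisher transformed (z = atanh r), and each pre-registered
contrast selects one cell of the resulting 4 x 4 similarity matrix with
unit weight.  The four contrasts compare externally cued vs internally
chosen action and inhibition:

    Go vs NoGo, Choose-Go vs Choose-NoGo, Go vs Choose-Go,
    NoGo vs Choose-NoGo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .conditions import CONDITIONS

log = logging.getLogger(__name__)

#: |r| is clipped to this bound before atanh so z stays finite.
CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ContrastSpec:
    """A named off-diagonal cell of the similarity matrix."""

    name: str
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.pair
        if a not in CONDITIONS or b not in CONDITIONS:
            raise ValueError(f"unknown condition in pair {self.pair}")
        if a == b:
            raise ValueError("contrast cell must be off-diagonal")


#: The four pre-registered similarity contrasts.
DEFAULT_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec("Go_vs_NoGo", ("Go", "NoGo")),
    ContrastSpec("ChooseGo_vs_ChooseNoGo", ("ChooseGo", "ChooseNoGo")),
    ContrastSpec("Go_vs_ChooseGo", ("Go", "ChooseGo")),
    ContrastSpec("NoGo_vs_ChooseNoGo", ("NoGo", "ChooseNoGo")),
)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Per-subject 4 x 4 similarity on the Fisher-z scale.

    ``z`` and ``r`` are symmetric with the canonical condition order; the
    diagonal is not meaningful and excluded from all scoring.
    """

    z: np.ndarray
    r: np.ndarray
    n_voxels: int

    def cell(self, cond_a: str, cond_b: str) -> float:
        i, j = CONDITIONS.index(cond_a), CONDITIONS.index(cond_b)
        if i == j:
            raise ValueError(f"diagonal cell ({cond_a}) has no similarity score")
        return float(self.z[i, j])


def pattern_correlation(patterns: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of condition rows across voxels.

    Parameters
    ----------
    patterns
        (4, V) matrix, rows in canonical condition order, V >= 2.

    Raises
    ------
    ValueError
        If a condition row has zero variance (named in the message).
    """
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[0] != len(CONDITIONS):
        raise ValueError(f"expected (4, V) pattern matrix, got {P.shape}")
    if P.shape[1] < 2:
        raise ValueError("need at least 2 voxels")
    sd = P.std(axis=1)
    # constant rows can carry float residue of order eps * |value|
    tol = 1e-10 * (np.abs(P).max(axis=1) + 1.0)
    dead = [CONDITIONS[i] for i in np.nonzero(sd <= tol)[0]]
    if dead:
        raise ValueError(f"zero-variance pattern for condition(s): {dead}")
    R = np.corrcoef(P)
    np.fill_diagonal(R, 1.0)
    return R


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher transform z = atanh(r), clipping |r| to 1 - 1e-7.

    Values with |r| > 1 raise; |r| hitting the clip bound is logged.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError(f"|r| > 1 in {r!r}")
    n_clip = int(np.sum(np.abs(arr) > CLIP))
    if n_clip:
        log.warning("fisher_z: clipped %d correlation(s) at |r| = 1 - 1e-7", n_clip)
    z = np.arctanh(np.clip(arr, -CLIP, CLIP))
    return z if z.ndim else float(z)


def similarity_matrix(patterns: np.ndarray) -> SimilarityMatrix:
    """Full per-subject similarity: correlate, Fisher transform."""
    R = pattern_correlation(patterns)
    # diagonal r = 1 is undefined similarity; zero it out before the
    # transform so the clip warning only ever reflects real cells
    Z = np.asarray(fisher_z(np.where(np.eye(len(R), dtype=bool), 0.0, R)))
    np.fill_diagonal(Z, np.nan)
    return SimilarityMatrix(z=Z, r=R, n_voxels=patterns.shape[1])


def contrast_score(simmatrix: SimilarityMatrix, contrast: ContrastSpec) -> float:
    """The single (1)-weighted cell of the similarity matrix.

    Equals the symmetric cell by construction.
    """
    return simmatrix.cell(*contrast.pair)
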