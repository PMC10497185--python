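"""First-level general linear model over concatenated runs.

The model mirrors an event-related single-subject analysis with run
concatenation: one HRF-convolved 0.5 s boxcar regressor per outcome
condition present (Go, NoGo-correct, Choose-Go, Choose-NoGo, plus Go
omissions and NoGo errors when they occurred), a tic regressor when tic
events are supplied, a run-transition regressor marking the first volume
of runs 2 and 3, six motion-parameter regressors, one constant column per
run, and an optional per-run discrete-cosine high-pass basis.

Estimation is ordinary least squares per voxel — no autoregressive
pre-whitening and no default high-pass filter, so the estimator is exact
and directly testable; both can be switched on where desired.  The
outputs of interest are single-regressor t-maps for the four analysed
conditions against the implicit inter-trial baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, OUTCOME_CONDITIONS, OUTCOME_TO_CONDITION
from .grid import VolumeGrid
from .hrf import canonical_hrf
from .synthetic import MODEL_DURATION, SessionDesign, _event_regressor

log = logging.getLogger(__name__)

#: Column order for task regressors.
_TASK_ORDER = list(OUTCOME_CONDITIONS)


@dataclass
class DesignMatrix:
    """Named design matrix over the concatenated analysed volumes."""

    frame: pd.DataFrame  # rows: volumes, columns: named regressors
    frame_times: np.ndarray  # seconds on the session clock
    run_lengths: tuple[int, ...]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)


@dataclass
class GLMResult:
    """Per-voxel OLS estimates and everything needed for t-contrasts."""

    betas: dict[str, np.ndarray]  # column name -> map
    residual_variance: np.ndarray
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray  # (pseudo-)inverse of the normal equations
    shape: tuple[int, ...]  # spatial shape of the maps
    grid: VolumeGrid | None = None

    def t_map(self, column: str) -> np.ndarray:
        return contrast_tmap(self, column)

    def t_maps(self) -> dict[str, np.ndarray]:
        """t-maps for the four analysed conditions, keyed by condition."""
        out = {}
        for outcome, cond in OUTCOME_TO_CONDITION.items():
            out[cond] = contrast_tmap(self, outcome)
        return out


def build_design_matrix(
    session: SessionDesign,
    tic_events: list[list[tuple[float, float]]] | None = None,
    motion: list[np.ndarray] | None = None,
    high_pass_cutoff: float | None = None,
    microtime_dt: float = 0.1,
) -> DesignMatrix:
    """Build the concatenated-session design matrix.

    Parameters
    ----------
    session
        Trial timing with behavioural outcomes; onsets are per-run.
    tic_events
        Per-run (onset, duration) lists; a single ``tic`` column is added
        only when any run has events.
    motion
        Per-run (n_volumes, 6) realignment parameters; all-zero columns
        are dropped with a warning.
    high_pass_cutoff
        If given, adds a per-run discrete-cosine basis removing periods
        longer than this cutoff (s).  Off by default.
    """
    run_lengths = tuple(r.n_volumes for r in session.runs)
    n_total = sum(run_lengths)
    cols: dict[str, np.ndarray] = {}

    # task regressors: per outcome condition, concatenated across runs
    for outcome in _TASK_ORDER:
        pieces = []
        any_events = False
        for run in session.runs:
            onsets = np.asarray(
                [e.onset for e in run.events if e.outcome_condition == outcome]
            )
            frame_times = (np.arange(run.n_volumes) + 0.5) * run.tr
            if len(onsets):
                any_events = True
                for o in onsets:
                    if not 0 <= o < run.duration:
                        raise ValueError(
                            f"event onset {o:.2f}s outside run of {run.duration:.2f}s"
                        )
                x = _event_regressor(
                    onsets,
                    np.full(len(onsets), MODEL_DURATION),
                    frame_times,
                    run.duration,
                    dt=microtime_dt,
                )
            else:
                x = np.zeros(run.n_volumes)
            pieces.append(x)
        if any_events:
            cols[outcome] = np.concatenate(pieces)

    # tic regressor
    if tic_events is not None and any(len(r) for r in tic_events):
        pieces = []
        for run, evs in zip(session.runs, tic_events):
            frame_times = (np.arange(run.n_volumes) + 0.5) * run.tr
            if evs:
                x = _event_regressor(
                    np.asarray([o for o, _ in evs]),
                    np.asarray([d for _, d in evs]),
                    frame_times,
                    run.duration,
                    dt=microtime_dt,
                )
            else:
                x = np.zeros(run.n_volumes)
            pieces.append(x)
        cols["tic"] = np.concatenate(pieces)

    # run-transition regressor: first volume of runs 2..n
    trans = np.zeros(n_total)
    offset = 0
    for i, L in enumerate(run_lengths):
        if i > 0:
            trans[offset] = 1.0
        offset += L
    if len(run_lengths) > 1:
        cols["run_transition"] = trans

    # motion regressors
    if motion is not None:
        mats = [np.asarray(m, dtype=float) for m in motion]
        for m, L in zip(mats, run_lengths):
            if m.shape != (L, 6):
                raise ValueError(f"motion must be (n_volumes, 6); got {m.shape}")
        mot = np.concatenate(mats, axis=0)
        for j in range(6):
            col = mot[:, j]
            if np.allclose(col, 0.0):
                log.warning("dropping all-zero motion column %d", j + 1)
                continue
            cols[f"motion{j + 1}"] = col

    # run constants (disjoint indicators)
    offset = 0
    for i, L in enumerate(run_lengths):
        c = np.zeros(n_total)
        c[offset:offset + L] = 1.0
        cols[f"run{i + 1}_constant"] = c
        offset += L

    # optional per-run discrete-cosine high-pass basis
    if high_pass_cutoff is not None:
        offset = 0
        for i, (run, L) in enumerate(zip(session.runs, run_lengths)):
            n_basis = int(math.floor(2 * run.duration / high_pass_cutoff))
            for k in range(1, n_basis + 1):
                c = np.zeros(n_total)
                t = (np.arange(L) + 0.5) / L
                c[offset:offset + L] = np.cos(np.pi * k * t)
                cols[f"run{i + 1}_cos{k}"] = c
            offset += L

    frame_times = []
    t0 = 0.0
    for run in session.runs:
        frame_times.append((np.arange(run.n_volumes) + 0.5) * run.tr + t0)
        t0 += run.duration
    return DesignMatrix(
        frame=pd.DataFrame(cols),
        frame_times=np.concatenate(frame_times),
        run_lengths=run_lengths,
    )


def fit_glm(
    bold: list[np.ndarray] | np.ndarray,
    design: DesignMatrix,
    discard_initial: int = 0,
    grid: VolumeGrid | None = None,
) -> GLMResult:
    """Ordinary least squares per voxel over the concatenated runs.

    Parameters
    ----------
    bold
        Either a list of per-run arrays with time on the last axis (4-D
        volumes or 2-D voxel x time), or a single pre-concatenated array.
    design
        The session design matrix; rows must equal the concatenated
        analysed volume count after discarding.
    discard_initial
        Number of initial (steady-state) volumes to drop from each run
        before fitting.

    Notes
    -----
    No pre-whitening is applied; residual variance uses
    ``dof = volumes - rank(design)``.  A rank-deficient design is fitted
    with the pseudo-inverse and a warning.
    """
    if isinstance(bold, np.ndarray):
        runs = [bold]
    else:
        runs = list(bold)
    runs = [np.asarray(r)[..., discard_initial:] for r in runs]
    spatial_shape = runs[0].shape[:-1]
    for r in runs:
        if r.shape[:-1] != spatial_shape:
            raise ValueError("all runs must share the same spatial shape")
    lengths = tuple(r.shape[-1] for r in runs)
    if len(runs) > 1 and lengths != design.run_lengths:
        raise ValueError(
            f"per-run volume counts {lengths} do not match design "
            f"{design.run_lengths} (after discarding {discard_initial})"
        )
    Y = np.concatenate([r.reshape(-1, r.shape[-1]) for r in runs], axis=1).T
    X = design.matrix
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"BOLD has {Y.shape[0]} volumes but design has {n} rows")

    rank = int(np.linalg.matrix_rank(X))
    if rank < p:
        log.warning("design matrix is rank deficient (rank %d < %d columns); "
                    "using pseudo-inverse", rank, p)
    pinv = np.linalg.pinv(X)
    B = pinv @ Y  # p x V
    resid = Y - X @ B
    dof = n - rank
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    # clamp float residue of perfectly fitted voxels to an exact zero
    ss_res = (resid**2).sum(axis=0)
    ss_y = (Y**2).sum(axis=0)
    ss_res[ss_res <= 1e-20 * np.maximum(ss_y, 1e-300)] = 0.0
    resvar = ss_res / dof
    xtx_inv = pinv @ pinv.T  # equals (X'X)^+ for the pseudo-inverse
    betas = {
        name: B[j].reshape(spatial_shape) for j, name in enumerate(design.columns)
    }
    return GLMResult(
        betas=betas,
        residual_variance=resvar.reshape(spatial_shape),
        dof=dof,
        design=design,
        xtx_inv=xtx_inv,
        shape=spatial_shape,
        grid=grid,
    )


def contrast_tmap(result: GLMResult, column_name: str) -> np.ndarray:
    """Single-regressor t-map: t = beta / SE(beta) for the named column.

    The contrast vector is the unit vector on the column; SE comes from
    the residual variance and the normal-equations (pseudo-)inverse.
    Voxels with zero residual variance yield t = 0 where beta = 0 and
    ±inf otherwise.
    """
    cols = result.design.columns
    if column_name not in cols:
        raise KeyError(
            f"no column {column_name!r}; available: {cols}"
        )
    j = cols.index(column_name)
    var_scale = result.xtx_inv[j, j]
    beta = result.betas[column_name]
    beta = np.asarray(beta, dtype=float)
    se = np.sqrt(result.residual_variance * var_scale)
    ok = se > 0
    t = np.zeros_like(beta)
    t[ok] = beta[ok] / se[ok]
    # zero-residual voxels: beta at float-residue level counts as zero
    beta_tol = 1e-10 * (1.0 + np.abs(beta).max())
    degenerate = ~ok & (np.abs(beta) > beta_tol)
    t[degenerate] = np.sign(beta[degenerate]) * np.inf
    return t
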