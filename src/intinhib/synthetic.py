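"""Synthetic cohorts for the intentional-inhibition fMRI study design.

This module generates everything the downstream analysis consumes — trial
sequences, jittered inter-trial intervals, behavioural outcomes, multi-voxel
BOLD volumes with a planted representational geometry, tic events, motion
parameters and symptom scores — so the whole pipeline runs and is testable
without any real scan.

Design being emulated
---------------------
A session comprises 3 runs of 288 trials (864 total: 432 Go, 144 NoGo,
288 Choose), 800 ms cues, ITIs jittered over {1000, 1130, 1250, 1380,
1500} ms at proportions 35/30/20/10/5 %, TR 2.52 s, 250 analysed volumes
per run (5 initial volumes discarded for steady-state magnetisation).
Two groups are simulated: TS (Tourette syndrome; default n=23, with tic
events, symptom scores and medication status) and CN (comparison; default
n=21).

Signal model (invented plumbing, not physics): each analysed outcome
condition has a voxel pattern over the ROI; patterns are Gaussian mixtures
constructed so their expected pairwise Pearson correlation equals a target
similarity matrix.  Voxel time series are the sum of HRF-convolved 0.5 s
event boxcars scaled by the planted patterns, low-frequency drift, a
motion-correlated component, tic-locked responses (TS only) and white
noise.  Outside the ROI only drift and noise are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .conditions import (
    CONDITIONS,
    InvalidConfigError,
    OUTCOME_CONDITIONS,
    RESOLUTION,
    TRIAL_TYPES,
)
from .grid import VolumeGrid, default_grid
from .hrf import canonical_hrf
from .roi import DEFAULT_ROIS, ROISpec, make_sphere_mask

# ---------------------------------------------------------------------------
# Study constants
# ---------------------------------------------------------------------------

CUE_DURATION = 0.8  # s, cue on screen
MODEL_DURATION = 0.5  # s, event duration used for signal generation and GLM
TR = 2.52  # s
N_RUNS = 3
ANALYSED_VOLUMES_PER_RUN = 250
DISCARDED_VOLUMES_PER_RUN = 5

#: Per-session trial counts: 432 Go (50%), 144 NoGo (17%), 288 Choose (33%).
SESSION_COUNTS: dict[str, int] = {"Go": 432, "NoGo": 144, "Choose": 288}
#: Equal split of the session counts across the three runs.
RUN_COUNTS: dict[str, int] = {"Go": 144, "NoGo": 48, "Choose": 96}

#: Jittered ITI support (s) and proportions.
ITI_SUPPORT: tuple[float, ...] = (1.000, 1.130, 1.250, 1.380, 1.500)
ITI_PROPORTIONS: tuple[float, ...] = (0.35, 0.30, 0.20, 0.10, 0.05)

#: Cap on identical-cue run length during pseudo-randomisation.
MAX_RUN_LENGTH = 6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialEvent:
    """One trial with its behavioural resolution.

    ``onset`` is seconds from the start of the first analysed volume of the
    run; ``duration`` is the 0.8 s cue; ``rt`` is None for withheld
    responses and omissions.
    """

    onset: float
    duration: float
    trial_type: str
    response: str
    outcome_condition: str
    rt: float | None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.outcome_condition not in OUTCOME_CONDITIONS:
            raise ValueError(f"unknown outcome {self.outcome_condition!r}")
        expected = RESOLUTION[(self.trial_type, self.response)]
        if expected != self.outcome_condition:
            raise ValueError(
                f"({self.trial_type}, {self.response}) resolves to {expected}, "
                f"not {self.outcome_condition}"
            )


@dataclass(frozen=True)
class RunDesign:
    """One run: its trial events, ITIs and acquisition geometry."""

    events: tuple[TrialEvent, ...]
    itis: tuple[float, ...]
    n_volumes: int = ANALYSED_VOLUMES_PER_RUN
    tr: float = TR

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing within a run")

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr


@dataclass(frozen=True)
class SessionDesign:
    """A full three-run session for one subject."""

    runs: tuple[RunDesign, ...]
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(r.events) for r in self.runs)

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for run in self.runs:
            for ev in run.events:
                counts[ev.trial_type] = counts.get(ev.trial_type, 0) + 1
        return counts


@dataclass(frozen=True)
class BehaviourRates:
    """Behavioural outcome probabilities and reaction-time parameters.

    Defaults are the comparison-group means of the study design being
    emulated (%Choose-Go 53%, NoGo errors 3%, Go omissions 1%; RT means
    0.42 s Go, 0.48 s Choose-Go, 0.37 s NoGo error).  RTs are truncated
    normal on ``rt_bounds``.
    """

    p_choose_go: float = 0.53
    p_nogo_error: float = 0.03
    p_go_omission: float = 0.01
    go_rt: tuple[float, float] = (0.42, 0.04)
    choose_go_rt: tuple[float, float] = (0.48, 0.045)
    nogo_error_rt: tuple[float, float] = (0.37, 0.17)
    rt_bounds: tuple[float, float] = (0.1, 0.8)

    def __post_init__(self) -> None:
        for name in ("p_choose_go", "p_nogo_error", "p_go_omission"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")


#: TS-group behaviour (group means: %Choose-Go 56%, omissions 2%).
TS_RATES = BehaviourRates(p_choose_go=0.56, p_go_omission=0.02,
                          go_rt=(0.434, 0.04), choose_go_rt=(0.488, 0.043))
CN_RATES = BehaviourRates()


@dataclass(frozen=True)
class ConditionPatternSet:
    """Per-condition voxel patterns with their intended similarity.

    ``patterns`` maps each of the four analysed conditions to a vector of
    per-voxel response amplitudes; ``target_similarity`` is the 4 x 4
    Pearson correlation matrix the construction aims for in expectation.
    """

    patterns: dict[str, np.ndarray]
    target_similarity: np.ndarray

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.patterns]
        if missing:
            raise InvalidConfigError(f"patterns missing conditions {missing}")

    @property
    def n_voxels(self) -> int:
        return len(next(iter(self.patterns.values())))

    def as_matrix(self) -> np.ndarray:
        """4 x V matrix in canonical condition order."""
        return np.stack([self.patterns[c] for c in CONDITIONS], axis=0)


@dataclass(frozen=True)
class BoldNoise:
    """Additive nuisance components of the simulated BOLD signal.

    voxel_sd
        SD of i.i.d. Gaussian noise per voxel per volume.
    drift_amplitude
        SD of the random coefficients of a 3-component low-frequency
        cosine drift per voxel per run.
    motion_sd
        SD of per-voxel loadings on the 6 motion parameters (in-ROI).
    tic_amplitude
        Scale of the tic-locked HRF response (in-ROI, TS subjects).
    motion_step_sd
        SD of the per-volume random-walk step of each motion parameter.
    """

    voxel_sd: float = 1.0
    drift_amplitude: float = 0.5
    motion_sd: float = 0.3
    tic_amplitude: float = 1.0
    motion_step_sd: float = 0.02


@dataclass
class SubjectRecord:
    """One simulated participant."""

    id: str
    group: str  # "TS" or "CN"
    session: SessionDesign
    bold: list[np.ndarray] | None  # per-run (x, y, z, t) arrays
    motion: list[np.ndarray]  # per-run (t, 6)
    tic_events: list[tuple[float, float]]  # (onset, duration), session clock
    ygtss_severity: int
    puts: int
    medication: str  # "medicated" | "unmedicated"
    n_tics: int
    patterns: ConditionPatternSet | None = None
    planted_z: float = math.nan  # subject-level common similarity shift

    def __post_init__(self) -> None:
        if self.group not in ("TS", "CN"):
            raise ValueError(f"group must be TS or CN, got {self.group!r}")
        if self.group == "CN" and self.tic_events:
            raise ValueError("CN subjects must have no tic events")
        if not 0 <= self.ygtss_severity <= 50:
            raise ValueError("YGTSS symptom severity must be within 0-50")


def _default_mean_z(group: str) -> np.ndarray:
    """Default group-mean Fisher-z similarity matrices.

    The four pre-registered pairs take the preSMA group means of the study
    being emulated (CN 1.596/1.461/1.402/1.209; TS 1.853/1.715/1.714/1.510
    for Go-NoGo, ChooseGo-ChooseNoGo, Go-ChooseGo, NoGo-ChooseNoGo); the
    two unreported pairs are filled with the mean of the four.
    """
    if group == "CN":
        gn, cgcn, gcg, ncn = 1.596, 1.461, 1.402, 1.209
    else:
        gn, cgcn, gcg, ncn = 1.853, 1.715, 1.714, 1.510
    fill = (gn + cgcn + gcg + ncn) / 4.0
    z = np.zeros((4, 4))
    z[0, 1] = z[1, 0] = gn
    z[0, 2] = z[2, 0] = gcg
    z[0, 3] = z[3, 0] = fill
    z[1, 2] = z[2, 1] = fill
    z[1, 3] = z[3, 1] = ncn
    z[2, 3] = z[3, 2] = cgcn
    return z


@dataclass(frozen=True)
class CohortConfig:
    """Ground truth for one simulated cohort.

    The defaults are the emulated study's conditions: 23 TS and 21 CN
    subjects, the full 3 x 288-trial session on a 250-volume run, group-mean
    Fisher-z similarity at the preSMA values, a between-subject similarity
    spread of 0.3 (z units, matching the observed group-difference t's),
    behaviour rates at the group means, and tic counts with mean ~161 and
    SD ~147 over the 30-min session.  ``scale`` parameters exist so tests
    can run the identical machinery on a smaller design.
    """

    n_ts: int = 23
    n_cn: int = 21
    mean_z_ts: np.ndarray = field(default_factory=lambda: _default_mean_z("TS"))
    mean_z_cn: np.ndarray = field(default_factory=lambda: _default_mean_z("CN"))
    subject_spread: float = 0.3
    amplitude: float = 6.0
    noise: BoldNoise = field(default_factory=BoldNoise)
    rates_ts: BehaviourRates = TS_RATES
    rates_cn: BehaviourRates = CN_RATES
    r_ygtss: float = 0.0
    r_puts: float = 0.0
    ygtss_mean: float = 26.0
    ygtss_sd: float = 9.0
    puts_mean: float = 23.0
    puts_sd: float = 7.0
    tic_rate: float = 161.0 / (N_RUNS * ANALYSED_VOLUMES_PER_RUN * TR)
    tic_dispersion: float = 1.2
    tic_duration: float = 0.3
    p_medicated: float = 9.0 / 23.0
    trials_per_run: dict[str, int] = field(default_factory=lambda: dict(RUN_COUNTS))
    n_volumes: int = ANALYSED_VOLUMES_PER_RUN
    tr: float = TR
    grid: VolumeGrid = field(default_factory=default_grid)
    roi: ROISpec = DEFAULT_ROIS[0]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ts < 2 or self.n_cn < 2:
            raise InvalidConfigError("group sizes must be >= 2")
        if abs(self.r_ygtss) >= 1 or abs(self.r_puts) >= 1:
            raise InvalidConfigError("|symptom correlation targets| must be < 1")


# ---------------------------------------------------------------------------
# Trial sequence / ITI / behaviour
# ---------------------------------------------------------------------------


def generate_trial_sequence(
    n_trials: int,
    counts: dict[str, int],
    seed: int | np.random.Generator,
    max_run_length: int = MAX_RUN_LENGTH,
) -> list[str]:
    """Pseudo-randomised trial-type sequence realising exact counts.

    The sequence is a uniform shuffle repaired so that no more than
    ``max_run_length`` identical cues occur consecutively.  Deterministic
    in ``seed``.

    Raises
    ------
    InvalidConfigError
        If the counts do not sum to ``n_trials``.
    """
    counts = {k: int(v) for k, v in counts.items()}
    if any(v < 0 for v in counts.values()):
        raise InvalidConfigError(f"negative counts: {counts}")
    if sum(counts.values()) != n_trials:
        raise InvalidConfigError(
            f"counts {counts} sum to {sum(counts.values())}, expected {n_trials}"
        )
    rng = np.random.default_rng(seed)
    seq = [t for t in TRIAL_TYPES for _ in range(counts.get(t, 0))]
    extra = [t for t in counts if t not in TRIAL_TYPES]
    if extra:
        raise InvalidConfigError(f"unknown trial types: {extra}")
    rng.shuffle(seq)
    _cap_run_lengths(seq, max_run_length, rng)
    return seq


def _cap_run_lengths(seq: list[str], cap: int, rng: np.random.Generator) -> None:
    """In-place repair: swap elements until no identical-type run exceeds cap."""
    if cap < 1 or len(set(seq)) < 2:
        return

    def first_violation() -> int | None:
        run = 1
        for i in range(1, len(seq)):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            if run > cap:
                return i
        return None

    def run_ok_at(j: int) -> bool:
        lo, hi = max(0, j - cap), min(len(seq), j + cap + 1)
        run = 1
        for k in range(lo + 1, hi):
            run = run + 1 if seq[k] == seq[k - 1] else 1
            if run > cap:
                return False
        return True

    for _ in range(100 * len(seq)):
        i = first_violation()
        if i is None:
            return
        for j in rng.permutation(len(seq)):
            j = int(j)
            if seq[j] == seq[i]:
                continue
            seq[i], seq[j] = seq[j], seq[i]
            if run_ok_at(i) and run_ok_at(j):
                break
            seq[i], seq[j] = seq[j], seq[i]
    raise RuntimeError("could not satisfy run-length cap")  # pragma: no cover


def generate_iti_sequence(n: int, seed: int | np.random.Generator) -> list[float]:
    """Jittered ITIs with *exact* counts per duration, order shuffled.

    Counts are the largest-remainder apportionment of the stated
    proportions (35/30/20/10/5 % of 1000/1130/1250/1380/1500 ms), so for n
    a multiple of 20 the empirical proportions equal the stated ones
    exactly.
    """
    if n < 1:
        raise InvalidConfigError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    raw = [p * n for p in ITI_PROPORTIONS]
    base = [math.floor(x) for x in raw]
    short = n - sum(base)
    # hand leftover slots to the largest fractional remainders
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - base[i], ITI_PROPORTIONS[i]),
                   reverse=True)
    for i in order[:short]:
        base[i] += 1
    itis = [d for d, c in zip(ITI_SUPPORT, base) for _ in range(c)]
    rng.shuffle(itis)
    return itis


def simulate_behaviour(
    trials: list[str],
    rates: BehaviourRates,
    seed: int | np.random.Generator,
    itis: list[float] | None = None,
) -> list[TrialEvent]:
    """Resolve a trial-type sequence into behavioural outcomes.

    Choose trials become Choose-Go with probability ``p_choose_go`` (else
    Choose-NoGo); Go trials become omissions with probability
    ``p_go_omission``; NoGo trials become commission errors with
    probability ``p_nogo_error``.  RTs are truncated-normal.  Onsets are
    laid out sequentially as cue (0.8 s) + ITI; if ``itis`` is not given
    it is generated from the same seed.
    """
    rng = np.random.default_rng(seed)
    if itis is None:
        itis = generate_iti_sequence(len(trials), rng)
    if len(itis) < len(trials) - 1:
        raise InvalidConfigError("need at least len(trials) - 1 ITIs")

    def trunc_rt(mean: float, sd: float) -> float:
        lo, hi = rates.rt_bounds
        for _ in range(100):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return float(x)
        return float(min(max(mean, lo), hi))  # pragma: no cover

    events: list[TrialEvent] = []
    onset = 0.0
    for k, t in enumerate(trials):
        if t == "Go":
            if rng.random() < rates.p_go_omission:
                response, rt = "withhold", None
            else:
                response, rt = "press", trunc_rt(*rates.go_rt)
        elif t == "NoGo":
            if rng.random() < rates.p_nogo_error:
                response, rt = "press", trunc_rt(*rates.nogo_error_rt)
            else:
                response, rt = "withhold", None
        elif t == "Choose":
            if rng.random() < rates.p_choose_go:
                response, rt = "press", trunc_rt(*rates.choose_go_rt)
            else:
                response, rt = "withhold", None
        else:
            raise InvalidConfigError(f"unknown trial type {t!r}")
        events.append(
            TrialEvent(
                # microsecond rounding keeps onsets exact under file
                # round-trips (they are sums of ms-resolution intervals)
                onset=round(onset, 6),
                duration=CUE_DURATION,
                trial_type=t,
                response=response,
                outcome_condition=RESOLUTION[(t, response)],
                rt=rt,
            )
        )
        if k < len(trials) - 1:
            onset += CUE_DURATION + itis[k]
    return events


def build_session(
    seed: int,
    rates: BehaviourRates = CN_RATES,
    trials_per_run: dict[str, int] | None = None,
    n_volumes: int = ANALYSED_VOLUMES_PER_RUN,
    tr: float = TR,
    n_runs: int = N_RUNS,
) -> SessionDesign:
    """Assemble a full session: per-run sequences, ITIs and outcomes."""
    trials_per_run = dict(trials_per_run or RUN_COUNTS)
    n_per_run = sum(trials_per_run.values())
    ss = np.random.SeedSequence(seed)
    runs = []
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        trials = generate_trial_sequence(n_per_run, trials_per_run, rng)
        itis = generate_iti_sequence(n_per_run, rng)
        events = simulate_behaviour(trials, rates, rng, itis=itis)
        last_end = events[-1].onset + CUE_DURATION
        if last_end > n_volumes * tr:
            raise InvalidConfigError(
                f"run of {n_per_run} trials (~{last_end:.0f}s) does not fit in "
                f"{n_volumes} volumes x TR {tr}s"
            )
        runs.append(RunDesign(tuple(events), tuple(itis), n_volumes, tr))
    return SessionDesign(tuple(runs), seed=seed)


# ---------------------------------------------------------------------------
# Patterns and BOLD
# ---------------------------------------------------------------------------


def build_condition_patterns(
    n_voxels: int,
    target_similarity: np.ndarray,
    seed: int | np.random.Generator,
) -> ConditionPatternSet:
    """Gaussian patterns whose expected pairwise Pearson correlation equals
    the target matrix.

    Patterns are linear mixtures ``P = A G`` of i.i.d. standard-normal
    voxel components ``G`` with ``A Aᵀ = R`` (symmetric matrix square
    root), the general form of the shared/unique decomposition
    ``√ρ·g + √(1−ρ)·u`` for a common-ρ target.  A rank-deficient but PSD
    target (e.g. an off-diagonal of exactly 1) is honoured and yields
    duplicated patterns.

    Raises
    ------
    InvalidConfigError
        If the target is not a valid (symmetric, unit-diagonal, PSD)
        correlation matrix.
    """
    R = np.asarray(target_similarity, dtype=float)
    if R.shape != (len(CONDITIONS), len(CONDITIONS)):
        raise InvalidConfigError(f"target must be 4x4, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise InvalidConfigError("target similarity must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise InvalidConfigError("target similarity must have unit diagonal")
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise InvalidConfigError(
            f"target similarity is not positive semi-definite (min eig {w.min():.3g})"
        )
    A = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((len(CONDITIONS), n_voxels))
    P = A @ G
    return ConditionPatternSet(
        patterns={c: P[i] for i, c in enumerate(CONDITIONS)},
        target_similarity=R,
    )


def generate_motion(
    n_volumes: int,
    seed: int | np.random.Generator,
    step_sd: float = 0.02,
) -> np.ndarray:
    """Six realignment-parameter traces as slow random walks, (t, 6)."""
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.normal(0.0, step_sd, size=(n_volumes, 6)), axis=0)


def generate_tic_events(
    session: SessionDesign,
    rate: float,
    seed: int | np.random.Generator,
    duration: float = 0.3,
) -> list[list[tuple[float, float]]]:
    """Homogeneous-Poisson tic events per run as (onset, duration) lists."""
    rng = np.random.default_rng(seed)
    out = []
    for run in session.runs:
        n = rng.poisson(rate * run.duration)
        onsets = np.sort(rng.uniform(0.0, run.duration, size=n))
        out.append([(float(o), duration) for o in onsets])
    return out


def _event_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    frame_times: np.ndarray,
    run_duration: float,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar sampled at frame times (microtime grid ``dt``)."""
    n_micro = int(math.ceil(run_duration / dt)) + 1
    box = np.zeros(n_micro)
    for o, d in zip(onsets, durations):
        # epsilon keeps bin assignment stable against float residue
        i0 = int(math.floor(o / dt + 0.5 + 1e-9))
        i1 = max(i0 + 1, int(math.floor((o + d) / dt + 0.5 + 1e-9)))
        box[i0:min(i1, n_micro)] += 1.0
    h = canonical_hrf(np.arange(0.0, 32.0 + dt, dt))
    conv = np.convolve(box, h)[:n_micro] * dt
    return np.interp(frame_times, np.arange(n_micro) * dt, conv)


def simulate_bold(
    design: SessionDesign,
    patterns: ConditionPatternSet,
    grid: VolumeGrid,
    roi_mask: np.ndarray,
    noise: BoldNoise | None = None,
    tic_events: list[list[tuple[float, float]]] | None = None,
    motion: list[np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
    amplitude: float = 6.0,
    n_discard: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Simulate per-run 4-D BOLD volumes with the planted geometry.

    In-ROI voxel time series are the sum of HRF-convolved 0.5 s event
    boxcars weighted by ``amplitude`` times the condition's planted voxel
    pattern, plus tic-locked responses, a motion-correlated component,
    low-frequency drift and white noise.  Nuisance outcomes (omissions,
    commission errors) receive their own random patterns.  Outside the ROI
    only drift and noise are present.  If ``n_discard`` > 0, that many
    pre-task dummy volumes are prepended to each run (mimicking volumes
    later discarded for steady-state magnetisation).

    Returns
    -------
    (runs, motion)
        ``runs``: list of (x, y, z, t) float32 arrays; ``motion``: the
        (analysed-volumes, 6) parameter table per run actually used.
    """
    noise = noise or BoldNoise()
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != grid.shape:
        raise ValueError(
            f"mask shape {roi_mask.shape} does not match grid shape {grid.shape}"
        )
    n_roi = int(roi_mask.sum())
    if patterns.n_voxels != n_roi:
        raise ValueError(
            f"patterns have {patterns.n_voxels} voxels but mask has {n_roi}"
        )
    rng = np.random.default_rng(seed)
    P = patterns.as_matrix()  # 4 x V
    # fixed nuisance patterns per subject (shared across runs)
    nuis_P = {c: rng.standard_normal(n_roi) for c in ("GoOmission", "NoGoError")}
    tic_P = rng.standard_normal(n_roi)

    runs_out: list[np.ndarray] = []
    motion_out: list[np.ndarray] = []
    for r_idx, run in enumerate(design.runs):
        T = run.n_volumes
        frame_times = (np.arange(T) + 0.5) * run.tr
        roi_ts = np.zeros((n_roi, T))
        # task signal: planted patterns for analysed outcomes, random for nuisance
        by_outcome: dict[str, list[float]] = {}
        for ev in run.events:
            by_outcome.setdefault(ev.outcome_condition, []).append(ev.onset)
        for outcome, onsets in by_outcome.items():
            x = _event_regressor(
                np.asarray(onsets),
                np.full(len(onsets), MODEL_DURATION),
                frame_times,
                run.duration,
            )
            if outcome in ("GoOmission", "NoGoError"):
                pat = nuis_P[outcome]
            else:
                from .conditions import OUTCOME_TO_CONDITION

                pat = P[CONDITIONS.index(OUTCOME_TO_CONDITION[outcome])]
            roi_ts += amplitude * np.outer(pat, x)
        # tic-locked responses
        if tic_events is not None and tic_events[r_idx]:
            t_on = np.asarray([o for o, _ in tic_events[r_idx]])
            t_dur = np.asarray([d for _, d in tic_events[r_idx]])
            x_tic = _event_regressor(t_on, t_dur, frame_times, run.duration)
            roi_ts += noise.tic_amplitude * np.outer(tic_P, x_tic)
        # motion-correlated component
        if motion is not None:
            mot = np.asarray(motion[r_idx], dtype=float)
        else:
            mot = generate_motion(T, rng, noise.motion_step_sd)
        if mot.shape != (T, 6):
            raise ValueError(f"motion for run {r_idx} must be ({T}, 6)")
        loadings = rng.normal(0.0, noise.motion_sd, size=(6, n_roi))
        roi_ts += (mot @ loadings).T
        # whole-volume drift + noise
        vol = np.empty(grid.shape + (T,), dtype=np.float32)
        n_all = grid.n_voxels
        tt = frame_times / run.duration  # in [0, 1)
        drift_basis = np.stack(
            [np.cos(np.pi * k * tt) for k in (1, 2, 3)], axis=0
        )  # 3 x T
        coefs = rng.normal(0.0, noise.drift_amplitude, size=(n_all, 3))
        flat = coefs @ drift_basis
        flat += rng.normal(0.0, noise.voxel_sd, size=(n_all, T))
        flat = flat.reshape(grid.shape + (T,))
        vol[:] = flat
        vol[roi_mask] += roi_ts.astype(np.float32)
        if n_discard > 0:
            dummy = rng.normal(
                0.0, noise.voxel_sd, size=grid.shape + (n_discard,)
            ).astype(np.float32)
            vol = np.concatenate([dummy, vol], axis=-1)
        runs_out.append(vol)
        motion_out.append(mot)
    return runs_out, motion_out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _symptom_score(
    delta_std: float,
    target_r: float,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
) -> int:
    """Gaussian linear mixture with correlation ``target_r`` to the subject's
    standardised similarity shift, clipped and rounded to the scale range."""
    eps = rng.standard_normal()
    raw = mean + sd * (target_r * delta_std + math.sqrt(1 - target_r**2) * eps)
    return int(round(min(max(raw, lo), hi)))


def simulate_subject(
    config: CohortConfig,
    group: str,
    subject_seed: np.random.SeedSequence,
    subject_id: str,
    roi_mask: np.ndarray,
    keep_bold: bool = True,
) -> SubjectRecord:
    """Simulate one participant end to end under a cohort configuration."""
    rng = np.random.default_rng(subject_seed)
    mean_z = config.mean_z_ts if group == "TS" else config.mean_z_cn
    rates = config.rates_ts if group == "TS" else config.rates_cn
    # subject-level similarity: common Fisher-z shift of all pairs
    delta = rng.normal(0.0, config.subject_spread)
    z_subj = mean_z + delta
    R_subj = np.tanh(z_subj)
    np.fill_diagonal(R_subj, 1.0)
    # guard PSD: clip tiny negative eigenvalues introduced by the shift
    w, V = np.linalg.eigh(R_subj)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        R_subj = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R_subj))
        R_subj = R_subj / np.outer(d, d)
        np.fill_diagonal(R_subj, 1.0)

    session = build_session(
        seed=int(rng.integers(2**31 - 1)),
        rates=rates,
        trials_per_run=config.trials_per_run,
        n_volumes=config.n_volumes,
        tr=config.tr,
    )
    n_roi = int(np.asarray(roi_mask).sum())
    patterns = build_condition_patterns(n_roi, R_subj, rng)

    tic_events_runs: list[list[tuple[float, float]]] = [[] for _ in session.runs]
    if group == "TS":
        # gamma-mixed Poisson rate -> negative-binomial dispersed counts
        k = config.tic_dispersion
        subj_rate = rng.gamma(shape=k, scale=config.tic_rate / k)
        tic_events_runs = generate_tic_events(
            session, subj_rate, rng, config.tic_duration
        )
    bold, motion = simulate_bold(
        session,
        patterns,
        config.grid,
        roi_mask,
        noise=config.noise,
        tic_events=tic_events_runs if group == "TS" else None,
        seed=rng,
        amplitude=config.amplitude,
    )
    n_tics = sum(len(r) for r in tic_events_runs)
    delta_std = delta / config.subject_spread if config.subject_spread > 0 else 0.0
    if group == "TS":
        ygtss = _symptom_score(
            delta_std, config.r_ygtss, config.ygtss_mean, config.ygtss_sd, 0, 50, rng
        )
        puts = _symptom_score(
            delta_std, config.r_puts, config.puts_mean, config.puts_sd, 9, 36, rng
        )
        medication = (
            "medicated" if rng.random() < config.p_medicated else "unmedicated"
        )
    else:
        ygtss, puts, medication = 0, 0, "unmedicated"
    # flatten per-run tic lists to session clock for the record
    tics_flat: list[tuple[float, float]] = []
    t0 = 0.0
    for run, evs in zip(session.runs, tic_events_runs):
        tics_flat.extend((t0 + o, d) for o, d in evs)
        t0 += run.duration
    return SubjectRecord(
        id=subject_id,
        group=group,
        session=session,
        bold=bold if keep_bold else None,
        motion=motion,
        tic_events=tics_flat,
        ygtss_severity=ygtss,
        puts=puts,
        medication=medication,
        n_tics=n_tics,
        patterns=patterns,
        planted_z=delta,
    )


def iter_subjects(config: CohortConfig, keep_bold: bool = True):
    """Yield the cohort's subjects one at a time (TS first, then CN)."""
    roi_mask = make_sphere_mask(config.roi, config.grid)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_ts + config.n_cn)
    for i in range(config.n_ts):
        yield simulate_subject(
            config, "TS", children[i], f"ts{i + 1:02d}", roi_mask, keep_bold
        )
    for i in range(config.n_cn):
        yield simulate_subject(
            config, "CN", children[config.n_ts + i], f"cn{i + 1:02d}", roi_mask,
            keep_bold,
        )


def generate_cohort(config: CohortConfig, keep_bold: bool = True) -> list[SubjectRecord]:
    """Simulate the full cohort (defaults: 23 TS + 21 CN subjects)."""
    return list(iter_subjects(config, keep_bold=keep_bold))
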