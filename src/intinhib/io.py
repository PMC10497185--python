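"""File formats: NIfTI volumes, BIDS-style event tables, motion text.

The simulator writes one directory per subject:

    sub-<id>/
      bold_run-1.nii.gz ... bold_run-3.nii.gz   4-D BOLD, grid affine
      events_run-1.tsv ...                      onset, duration, trial_type,
                                                response, rt (tab-separated)
      motion_run-1.txt ...                      6 columns, whitespace
      tics_run-1.tsv ...                        onset, duration (TS only)

plus a cohort-level ``participants.tsv`` (id, group, ygtss, puts,
medication, n_tics).  The GLM stage reads these back; t-maps are written
as NIfTI-1 with the input grid's affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .conditions import RESOLUTION
from .grid import VolumeGrid
from .synthetic import (
    CUE_DURATION,
    RunDesign,
    SessionDesign,
    SubjectRecord,
)


def save_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write a 3-D or 4-D array as NIfTI-1 with the grid's affine."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float32), img.affine


def events_to_frame(run: RunDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset": [e.onset for e in run.events],
            "duration": [e.duration for e in run.events],
            "trial_type": [e.trial_type for e in run.events],
            "response": [e.response for e in run.events],
            "rt": [e.rt if e.rt is not None else "n/a" for e in run.events],
        }
    )


def frame_to_events(frame: pd.DataFrame) -> list:
    """Rebuild TrialEvents from an events table (outcome re-derived)."""
    from .synthetic import TrialEvent

    events = []
    for row in frame.itertuples(index=False):
        rt = None if (isinstance(row.rt, str) and row.rt == "n/a") else float(row.rt)
        events.append(
            TrialEvent(
                onset=float(row.onset),
                duration=float(row.duration),
                trial_type=str(row.trial_type),
                response=str(row.response),
                outcome_condition=RESOLUTION[(str(row.trial_type), str(row.response))],
                rt=rt,
            )
        )
    return events


def write_subject(subject: SubjectRecord, grid: VolumeGrid, out_dir: str | Path) -> Path:
    """Write one subject's BOLD, events, motion and tic files."""
    sub_dir = Path(out_dir) / f"sub-{subject.id}"
    sub_dir.mkdir(parents=True, exist_ok=True)
    if subject.bold is None:
        raise ValueError(f"subject {subject.id} carries no BOLD data")
    t0 = 0.0
    for i, run in enumerate(subject.session.runs, start=1):
        save_volume(subject.bold[i - 1], grid, sub_dir / f"bold_run-{i}.nii.gz")
        events_to_frame(run).to_csv(
            sub_dir / f"events_run-{i}.tsv", sep="\t", index=False
        )
        np.savetxt(sub_dir / f"motion_run-{i}.txt", subject.motion[i - 1], fmt="%.6f")
        run_tics = [
            (o - t0, d)
            for o, d in subject.tic_events
            if t0 <= o < t0 + run.duration
        ]
        pd.DataFrame(run_tics, columns=["onset", "duration"]).to_csv(
            sub_dir / f"tics_run-{i}.tsv", sep="\t", index=False
        )
        t0 += run.duration
    return sub_dir


def read_subject_session(
    sub_dir: str | Path, n_volumes: int, tr: float
) -> tuple[SessionDesign, list[np.ndarray], list[list[tuple[float, float]]]]:
    """Read a subject directory back into (session, motion, tic_events).

    BOLD volumes are loaded separately with :func:`load_volume` to keep
    memory under the caller's control.
    """
    sub_dir = Path(sub_dir)
    runs, motion, tics = [], [], []
    i = 1
    while (sub_dir / f"events_run-{i}.tsv").exists():
        frame = pd.read_csv(sub_dir / f"events_run-{i}.tsv", sep="\t")
        events = frame_to_events(frame)
        itis = tuple(
            round(b.onset - a.onset - CUE_DURATION, 3)
            for a, b in zip(events, events[1:])
        )
        runs.append(RunDesign(tuple(events), itis, n_volumes, tr))
        motion.append(np.loadtxt(sub_dir / f"motion_run-{i}.txt"))
        tic_path = sub_dir / f"tics_run-{i}.tsv"
        if tic_path.exists():
            tf = pd.read_csv(tic_path, sep="\t")
            tics.append([(float(o), float(d)) for o, d in
                         zip(tf["onset"], tf["duration"])])
        else:
            tics.append([])
        i += 1
    if not runs:
        raise FileNotFoundError(f"no events_run-*.tsv under {sub_dir}")
    return SessionDesign(tuple(runs), seed=-1), motion, tics


def write_participants(subjects: list[SubjectRecord], out_dir: str | Path) -> Path:
    path = Path(out_dir) / "participants.tsv"
    pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "ygtss": [s.ygtss_severity for s in subjects],
            "puts": [s.puts for s in subjects],
            "medication": [s.medication for s in subjects],
            "n_tics": [s.n_tics for s in subjects],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
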