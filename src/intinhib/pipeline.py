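"""End-to-end orchestration: simulate → GLM → ROI → RSA → group stats.

:func:`run_pipeline` streams subjects one at a time (BOLD is dropped as
soon as a subject's similarity scores are computed), then runs the full
inferential layer: group t-tests with JZS Bayes factors and BH-FDR across
the six-ROI family of each contrast, symptom correlations in the TS
group, and the control analyses (tic-count correlations, medication
t-tests, 'greater vs overlapping' sub-group splits, behaviour-RSA
correlations).

:func:`stats_only_mode` recomputes p, FDR-adjusted p and BF10 columns
from summary statistics alone (t or r plus sample sizes) with no imaging
data — useful for auditing published tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditions import CONDITIONS
from .glm import build_design_matrix, fit_glm
from .grid import VolumeGrid
from .group_stats import (
    PriorSettings,
    bh_fdr,
    correlation_test,
    rejects_null,
    split_by_comparison_max,
    t_test_independent,
)
from .roi import DEFAULT_ROIS, ROISpec, make_sphere_mask, extract_patterns
from .rsa import DEFAULT_CONTRASTS, ContrastSpec, contrast_score, similarity_matrix
from .synthetic import CohortConfig, SubjectRecord, iter_subjects

log = logging.getLogger(__name__)

#: Behavioural measures tested against similarity scores.
BEHAVIOUR_MEASURES = (
    "pct_choose_go",
    "pct_nogo_errors",
    "pct_go_omissions",
    "choose_go_rt",
    "nogo_error_rt",
    "go_rt",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rois: tuple[ROISpec, ...] = DEFAULT_ROIS
    contrasts: tuple[ContrastSpec, ...] = DEFAULT_CONTRASTS
    priors: PriorSettings = field(default_factory=PriorSettings)
    out_dir: str | None = None
    log_level: str = "INFO"


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return repr(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def behaviour_summary(subject: SubjectRecord) -> dict[str, float]:
    """Per-subject behavioural measures from the session events."""
    events = [e for run in subject.session.runs for e in run.events]
    by_type = lambda t: [e for e in events if e.trial_type == t]  # noqa: E731
    go, nogo, choose = by_type("Go"), by_type("NoGo"), by_type("Choose")

    def mean_rt(evs, outcome):
        rts = [e.rt for e in evs if e.outcome_condition == outcome and e.rt is not None]
        return float(np.mean(rts)) if rts else math.nan

    return {
        "pct_choose_go": 100.0
        * sum(e.outcome_condition == "ChooseGo" for e in choose) / max(len(choose), 1),
        "pct_nogo_errors": 100.0
        * sum(e.outcome_condition == "NoGoError" for e in nogo) / max(len(nogo), 1),
        "pct_go_omissions": 100.0
        * sum(e.outcome_condition == "GoOmission" for e in go) / max(len(go), 1),
        "choose_go_rt": mean_rt(choose, "ChooseGo"),
        "nogo_error_rt": mean_rt(nogo, "NoGoError"),
        "go_rt": mean_rt(go, "Go"),
    }


def subject_similarity_records(
    subject: SubjectRecord,
    masks: dict[str, np.ndarray],
    contrasts: tuple[ContrastSpec, ...],
) -> list[dict]:
    """GLM-fit one subject and score every ROI x contrast cell."""
    design = build_design_matrix(
        subject.session,
        tic_events=_per_run_tics(subject),
        motion=subject.motion,
    )
    if subject.bold is None:
        raise ValueError(f"subject {subject.id} carries no BOLD data")
    result = fit_glm(subject.bold, design)
    tmaps = result.t_maps()
    rows = []
    behav = behaviour_summary(subject)
    for roi_name, mask in masks.items():
        patterns = extract_patterns(tmaps, mask)
        sim = similarity_matrix(patterns)
        for con in contrasts:
            i, j = CONDITIONS.index(con.pair[0]), CONDITIONS.index(con.pair[1])
            rows.append(
                {
                    "subject": subject.id,
                    "group": subject.group,
                    "roi": roi_name,
                    "contrast": con.name,
                    "z": contrast_score(sim, con),
                    "r": float(sim.r[i, j]),
                    "n_voxels": sim.n_voxels,
                    "ygtss": subject.ygtss_severity,
                    "puts": subject.puts,
                    "medication": subject.medication,
                    "n_tics": subject.n_tics,
                    **behav,
                }
            )
    return rows


def _per_run_tics(subject: SubjectRecord) -> list[list[tuple[float, float]]]:
    out, t0 = [], 0.0
    for run in subject.session.runs:
        out.append(
            [(o - t0, d) for o, d in subject.tic_events if t0 <= o < t0 + run.duration]
        )
        t0 += run.duration
    return out


def group_comparison_table(
    sim: pd.DataFrame, priors: PriorSettings
) -> pd.DataFrame:
    """Per ROI x contrast group inference (CN minus TS, mirroring the
    reported sign convention), FDR within the ROI family of each contrast."""
    rows = []
    for contrast, cdf in sim.groupby("contrast", sort=False):
        fam = []
        for roi, rdf in cdf.groupby("roi", sort=False):
            ts = rdf.loc[rdf.group == "TS", "z"].to_numpy()
            cn = rdf.loc[rdf.group == "CN", "z"].to_numpy()
            res = t_test_independent(cn, ts, priors.t_test_cauchy_scale)
            fam.append(
                {
                    "contrast": contrast,
                    "roi": roi,
                    "mean_z_cn": res.mean1,
                    "mean_z_ts": res.mean2,
                    "mean_r_cn": float(rdf.loc[rdf.group == "CN", "r"].mean()),
                    "mean_r_ts": float(rdf.loc[rdf.group == "TS", "r"].mean()),
                    "t": res.t,
                    "dof": res.dof,
                    "p": res.p_two_tailed,
                    "bf10": res.bf10,
                }
            )
        padj = bh_fdr(np.array([f["p"] for f in fam]))
        for f, pa in zip(fam, padj):
            f["p_fdr"] = float(pa)
            f["reject"] = rejects_null(f["p"], f["bf10"])
        rows.extend(fam)
    return pd.DataFrame(rows)


def symptom_correlation_table(
    sim: pd.DataFrame, priors: PriorSettings
) -> pd.DataFrame:
    """TS-only correlations of similarity with YGTSS and PUTS, FDR within
    the ROI family of each contrast x score."""
    ts = sim[sim.group == "TS"]
    rows = []
    for score in ("ygtss", "puts"):
        for contrast, cdf in ts.groupby("contrast", sort=False):
            fam = []
            for roi, rdf in cdf.groupby("roi", sort=False):
                res = correlation_test(
                    rdf["z"].to_numpy(),
                    rdf[score].to_numpy(dtype=float),
                    priors.correlation_beta_width,
                )
                fam.append(
                    {
                        "score": score,
                        "contrast": contrast,
                        "roi": roi,
                        "r": res.r,
                        "n": res.n,
                        "p": res.p_two_tailed,
                        "bf10": res.bf10,
                    }
                )
            padj = bh_fdr(np.array([f["p"] for f in fam]))
            for f, pa in zip(fam, padj):
                f["p_fdr"] = float(pa)
                f["reject"] = rejects_null(f["p"], f["bf10"])
            rows.extend(fam)
    return pd.DataFrame(rows)


def control_tables(
    sim: pd.DataFrame, priors: PriorSettings, roi: str = "preSMA"
) -> dict[str, pd.DataFrame]:
    """The reviewer-requested control analyses, all on one ROI's scores:
    tic-count correlations, medication t-tests, sub-group splits and
    behaviour-similarity correlations."""
    ts = sim[(sim.group == "TS") & (sim.roi == roi)]
    cn = sim[(sim.group == "CN") & (sim.roi == roi)]
    tic_rows, med_rows, split_rows, behav_rows = [], [], [], []
    for contrast, cdf in ts.groupby("contrast", sort=False):
        z = cdf["z"].to_numpy()
        # tic-frequency correlation
        try:
            res = correlation_test(z, cdf["n_tics"].to_numpy(dtype=float),
                                   priors.correlation_beta_width)
            tic_rows.append({"contrast": contrast, "roi": roi, "r": res.r,
                             "n": res.n, "p": res.p_two_tailed, "bf10": res.bf10})
        except ValueError as exc:
            log.warning("tic correlation skipped for %s: %s", contrast, exc)
        # medication status
        med = cdf.loc[cdf.medication == "medicated", "z"].to_numpy()
        unmed = cdf.loc[cdf.medication == "unmedicated", "z"].to_numpy()
        if len(med) >= 2 and len(unmed) >= 2:
            tres = t_test_independent(med, unmed, priors.t_test_cauchy_scale)
            med_rows.append(
                {"contrast": contrast, "roi": roi, "t": tres.t, "dof": tres.dof,
                 "p": tres.p_two_tailed, "bf10": tres.bf10,
                 "n_medicated": len(med), "n_unmedicated": len(unmed)}
            )
        else:
            log.warning("medication t-test skipped for %s (group too small)",
                        contrast)
        # greater / overlapping sub-groups relative to the comparison maximum
        z_cn = cn.loc[cn.contrast == contrast, "z"].to_numpy()
        parts = split_by_comparison_max(z, z_cn)
        split_rows.append(
            {"contrast": contrast, "roi": roi,
             "n_greater": len(parts["greater"]),
             "n_overlapping": len(parts["overlapping"]),
             "comparison_max": float(z_cn.max())}
        )
        # behaviour-similarity correlations (only when the table carries
        # behavioural measures; a file-based similarity table may not)
        for measure in BEHAVIOUR_MEASURES:
            if measure not in cdf.columns:
                continue
            vals = cdf[measure].to_numpy(dtype=float)
            keep = np.isfinite(vals)
            if keep.sum() < 3 or vals[keep].std() == 0:
                continue
            res = correlation_test(z[keep], vals[keep],
                                   priors.correlation_beta_width)
            behav_rows.append(
                {"contrast": contrast, "roi": roi, "measure": measure,
                 "r": res.r, "n": res.n, "p": res.p_two_tailed,
                 "bf10": res.bf10}
            )
    return {
        "tic_correlations": pd.DataFrame(tic_rows),
        "medication_ttests": pd.DataFrame(med_rows),
        "subgroup_splits": pd.DataFrame(split_rows),
        "behaviour_correlations": pd.DataFrame(behav_rows),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full flow and return the report bundle.

    Returns a dict with keys ``subject_similarity``, ``group_comparisons``,
    ``symptom_correlations``, the four control tables, and ``manifest``.
    Tables are also written as TSV when ``config.out_dir`` is set.
    """
    logging.basicConfig(level=config.log_level)
    grid = config.cohort.grid
    masks = {r.name: make_sphere_mask(r, grid) for r in config.rois}
    records: list[dict] = []
    stages = {"simulate_glm_rsa": 0}
    for subject in iter_subjects(config.cohort, keep_bold=True):
        records.extend(subject_similarity_records(subject, masks, config.contrasts))
        subject.bold = None  # free ~hundreds of MB at full scale
        stages["simulate_glm_rsa"] += 1
    sim = pd.DataFrame(records)
    bundle = {
        "subject_similarity": sim,
        "group_comparisons": group_comparison_table(sim, config.priors),
        "symptom_correlations": symptom_correlation_table(sim, config.priors),
        **control_tables(sim, config.priors, roi=config.rois[0].name),
    }
    bundle["manifest"] = {
        "config_hash": _config_hash(config),
        "seed": config.cohort.seed,
        "version": __version__,
        "stages": {**stages, "group_stats": len(bundle["group_comparisons"])},
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                           float_format="%.6f")
        (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    return bundle


def stats_only_mode(
    records: pd.DataFrame, priors: PriorSettings | None = None
) -> pd.DataFrame:
    """Recompute p, FDR-adjusted p and BF10 from summary statistics.

    Parameters
    ----------
    records
        One row per test with columns: ``family`` (FDR family label),
        ``label``, ``stat`` ('t' or 'r'), ``value``, ``n1`` and — for t
        tests — ``n2``.  For correlations ``n1`` is the sample size.
    priors
        Prior scales; defaults to the package defaults.

    Returns
    -------
    DataFrame with added ``p``, ``p_fdr``, ``bf10`` and ``reject`` columns,
    in the input row order.
    """
    from .group_stats import bf_correlation, jzs_bf_ttest, p_from_r, p_from_t

    priors = priors or PriorSettings()
    req = {"family", "label", "stat", "value", "n1"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"stats-only input missing columns: {sorted(missing)}")
    out = records.copy().reset_index(drop=True)
    p_col, bf_col = [], []
    for row in out.itertuples(index=False):
        if pd.isna(row.n1):
            raise ValueError(f"missing n for row {row.label!r}")
        n1 = int(row.n1)
        if row.stat == "t":
            n2 = getattr(row, "n2", None)
            if n2 is None or pd.isna(n2):
                raise ValueError(f"missing n2 for t-test row {row.label!r}")
            n2 = int(n2)
            p_col.append(p_from_t(row.value, n1 + n2 - 2))
            bf_col.append(jzs_bf_ttest(row.value, n1, n2,
                                       priors.t_test_cauchy_scale))
        elif row.stat == "r":
            p_col.append(p_from_r(row.value, n1))
            bf_col.append(bf_correlation(row.value, n1,
                                         priors.correlation_beta_width))
        else:
            raise ValueError(f"unknown stat kind {row.stat!r}")
    out["p"] = p_col
    out["bf10"] = bf_col
    out["p_fdr"] = np.nan
    for _, idx in out.groupby("family", sort=False).groups.items():
        out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out["reject"] = [rejects_null(p, b) for p, b in zip(out.p, out.bf10)]
    return out
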