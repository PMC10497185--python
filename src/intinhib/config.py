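"""YAML configuration for cohort simulation and pipeline runs.

A config file is a flat-ish YAML mapping; every field of
:class:`~intinhib.synthetic.CohortConfig` can be set under ``cohort:``
(arrays as nested lists), the analysis ROI set under ``rois:`` (list of
``{name, center, radius}``; omit for the six defaults) and prior scales
under ``priors:``.  The master ``seed`` is mandatory.

Example
-------
::

    seed: 7
    cohort:
      n_ts: 8
      n_cn: 8
      subject_spread: 0.3
      trials_per_run: {Go: 36, NoGo: 12, Choose: 24}
      n_volumes: 72
      grid: {shape: [9, 9, 9], voxel_size_mm: 3.0, origin_mm: [-12, 6, 36]}
      roi: {name: preSMA, center: [4, 18, 48], radius: 10}
    rois:
      - {name: preSMA, center: [4, 18, 48], radius: 10}
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import yaml

from .conditions import InvalidConfigError
from .grid import VolumeGrid
from .group_stats import PriorSettings
from .pipeline import PipelineConfig
from .roi import DEFAULT_ROIS, ROISpec
from .synthetic import BehaviourRates, BoldNoise, CohortConfig


def _as_tuple(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


def _roi_from_mapping(m: dict) -> ROISpec:
    return ROISpec(
        name=str(m["name"]),
        center_mni_mm=tuple(float(v) for v in m["center"]),
        radius_mm=float(m.get("radius", 10.0)),
    )


def cohort_config_from_mapping(m: dict, seed: int) -> CohortConfig:
    kwargs: dict = {"seed": seed}
    simple = {f.name for f in fields(CohortConfig)} - {
        "grid", "roi", "noise", "rates_ts", "rates_cn",
        "mean_z_ts", "mean_z_cn", "seed",
    }
    for key, value in m.items():
        if key in ("mean_z_ts", "mean_z_cn"):
            kwargs[key] = np.asarray(value, dtype=float)
        elif key == "grid":
            kwargs["grid"] = VolumeGrid(
                shape=tuple(int(v) for v in value["shape"]),
                voxel_size_mm=tuple(
                    float(v) for v in np.broadcast_to(value.get("voxel_size_mm", 3.0), 3)
                ),
                origin_mm=tuple(float(v) for v in value["origin_mm"]),
            )
        elif key == "roi":
            kwargs["roi"] = _roi_from_mapping(value)
        elif key == "noise":
            kwargs["noise"] = BoldNoise(**value)
        elif key in ("rates_ts", "rates_cn"):
            value = dict(value)
            for k in ("go_rt", "choose_go_rt", "nogo_error_rt", "rt_bounds"):
                if k in value:
                    value[k] = _as_tuple(value[k])
            kwargs[key] = BehaviourRates(**value)
        elif key in simple:
            kwargs[key] = value
        else:
            raise InvalidConfigError(f"unknown cohort config key {key!r}")
    return CohortConfig(**kwargs)


def load_pipeline_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Load a pipeline configuration from YAML.

    ``seed`` overrides the file's master seed; one of the two must be
    given.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if seed is None:
        seed = doc.get("seed")
    if seed is None:
        raise InvalidConfigError("a master seed is mandatory (file key 'seed' "
                                 "or --seed)")
    cohort = cohort_config_from_mapping(doc.get("cohort", {}), int(seed))
    rois = (
        tuple(_roi_from_mapping(r) for r in doc["rois"])
        if "rois" in doc
        else DEFAULT_ROIS
    )
    priors = PriorSettings(**doc.get("priors", {}))
    return PipelineConfig(
        cohort=cohort,
        rois=rois,
        priors=priors,
        out_dir=doc.get("out_dir"),
        log_level=str(doc.get("log_level", "INFO")),
    )
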