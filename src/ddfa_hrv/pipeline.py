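"""End-to-end orchestration: filter -> landscape -> surfaces -> features -> CV.

`run` executes the whole chain for a cohort manifest, caching the expensive
per-subject landscape stage on disk (keyed by a hash of the subject's
intervals and the landscape config), excluding subjects that fail a stage
with a logged reason, and writing a deterministic report so reruns with
identical inputs and config are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import density_surface, hr_surface
from .classify import CVConfig, CVReport, TaskSpec, nested_cv
from .ddfa import DDFAConfig, DDFALandscape, ddfa_landscape
from .features import FeatureConfig, build_features, feature_length, hr_stats
from .preprocess import FilterConfig, preprocess
from .rri_io import CohortManifest, RRISeries, read_rri

__all__ = ["PipelineConfig", "PipelineResult", "run"]

logger = logging.getLogger("ddfa_hrv.pipeline")


def _default_task() -> TaskSpec:
    return TaskSpec(mode="multiclass", classes=("healthy", "chf", "af"))


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the master seed."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    ddfa: DDFAConfig = field(default_factory=DDFAConfig)
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    task: TaskSpec = field(default_factory=_default_task)
    seed: int = 0
    cache: bool = True


@dataclass
class PipelineResult:
    report: CVReport
    features: pd.DataFrame
    excluded: Dict[str, str]
    out_dir: str


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "value"):  # enums
        return obj.value
    return obj


def config_hash(*parts) -> str:
    payload = json.dumps([_jsonable(p) for p in parts], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cached_landscape(
    series: RRISeries,
    wall_times: np.ndarray,
    config: PipelineConfig,
    cache_dir: Optional[str],
) -> DDFALandscape:
    if cache_dir is None:
        return ddfa_landscape(series, config.ddfa, wall_times=wall_times)
    key = config_hash(
        hashlib.sha256(series.intervals.tobytes()).hexdigest(), config.ddfa
    )
    path = os.path.join(cache_dir, f"{series.subject_id}_{key}.npz")
    if os.path.exists(path):
        with np.load(path) as data:
            logger.info("stage=ddfa subject=%s cache=hit", series.subject_id)
            return DDFALandscape(
                alpha=data["alpha"], t=data["t"], hr=data["hr"],
                scales=data["scales"], n_windows=data["n_windows"],
            )
    landscape = ddfa_landscape(series, config.ddfa, wall_times=wall_times)
    np.savez_compressed(
        path, alpha=landscape.alpha, t=landscape.t, hr=landscape.hr,
        scales=landscape.scales, n_windows=landscape.n_windows,
    )
    logger.info("stage=ddfa subject=%s cache=miss", series.subject_id)
    return landscape


def run(
    manifest: CohortManifest,
    config: Optional[PipelineConfig] = None,
    out_dir: str = "ddfa_hrv_results",
    base_dir: Optional[str] = None,
    series_map: Optional[Dict[str, RRISeries]] = None,
) -> PipelineResult:
    """Run the full pipeline for a cohort.

    Parameters
    ----------
    manifest
        Cohort listing; ``path`` entries are resolved against ``base_dir``
        unless the subject is supplied in-memory via ``series_map``.
    config
        Stage parameters; defaults reproduce the standard analysis.
    out_dir
        Output directory (created); receives ``report.json``,
        ``features.csv``, ``run_manifest.json`` and the landscape cache.
    """
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    cache_dir = os.path.join(out_dir, "cache") if config.cache else None
    if cache_dir:
        os.makedirs(cache_dir, exist_ok=True)

    task_classes = set(config.task.classes)
    rows: List[dict] = []
    labels: List[str] = []
    excluded: Dict[str, str] = {}
    for entry in manifest:
        if entry.group.value not in task_classes:
            continue
        try:
            if series_map is not None and entry.subject_id in series_map:
                series = series_map[entry.subject_id]
            else:
                path = entry.path
                if base_dir is not None:
                    path = os.path.join(base_dir, path)
                series = read_rri(path)
            filt = preprocess(series, config.filter)
            logger.info(
                "stage=preprocess subject=%s removed_median=%d removed_diff=%d",
                entry.subject_id, filt.n_removed_median, filt.n_removed_diff,
            )
            if filt.warning:
                raise ValueError(
                    f"poor quality: {filt.fraction_removed:.0%} of beats removed"
                )
            landscape = _cached_landscape(
                filt.filtered, filt.wall_times, config, cache_dir
            )
            surface = hr_surface(landscape)
            density = density_surface(landscape)
            stats = hr_stats(filt.filtered)
            vec = build_features(
                surface, density, stats, config.feature, entry.subject_id
            )
            rows.append(
                {"subject_id": entry.subject_id, "group": entry.group.value,
                 "surface": surface, "density": density, "stats": stats,
                 "vector": vec}
            )
            labels.append(entry.group.value)
        except Exception as exc:
            logger.warning("subject=%s excluded reason=%r", entry.subject_id, exc)
            excluded[entry.subject_id] = str(exc)
    if len(set(labels)) < 2:
        raise ValueError(
            f"fewer than 2 classes survive preprocessing (kept {sorted(set(labels))})"
        )

    frame = pd.DataFrame(
        [dict(zip(r["vector"].names, r["vector"].values)) for r in rows],
        index=[r["subject_id"] for r in rows],
    )
    frame.insert(0, "group", labels)
    frame.to_csv(os.path.join(out_dir, "features.csv"), index_label="subject_id")

    def feature_builder(resize) -> np.ndarray:
        fc = dataclasses.replace(
            config.feature, rest_size=tuple(resize[0]),
            exercise_size=tuple(resize[1]), density_size=tuple(resize[2]),
        )
        return np.stack(
            [
                build_features(
                    r["surface"], r["density"], r["stats"], fc, r["subject_id"]
                ).values
                for r in rows
            ]
        )

    features = np.stack([r["vector"].values for r in rows])
    needs_builder = "resize" in config.cv.param_grid
    report = nested_cv(
        None if needs_builder else features,
        labels,
        config.task,
        config.cv,
        feature_builder=feature_builder if needs_builder else None,
    )
    for fold in report.per_fold:
        logger.info("stage=cv chosen_params=%s", fold.chosen_params)

    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=1)
    run_manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "n_subjects": len(rows),
        "n_features": feature_length(config.feature),
        "excluded": excluded,
    }
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(run_manifest, fh, sort_keys=True, indent=1)
    return PipelineResult(
        report=report, features=frame, excluded=excluded, out_dir=out_dir
    )
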