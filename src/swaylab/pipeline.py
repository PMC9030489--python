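"""End-to-end pipeline: simulate -> measures -> effects -> classify."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .classify import ClassificationGrid
from .config import PipelineConfig, study_config_to_dict
from .effects import run_effects_battery
from .measures import MeasureOptions, compute_study_measures
from .simulate import simulate_study

log = logging.getLogger("swaylab")


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(
        {
            "study": study_config_to_dict(config.study),
            "cutoff_acc": config.cutoff_acc,
            "cutoff_cop": config.cutoff_cop,
            "filter_order": config.filter_order,
            "alpha": config.alpha,
            "sensor_configs": list(config.sensor_configs),
            "feature_sets": list(config.feature_sets),
            "classifiers": list(config.classifiers),
            "criterion": config.criterion,
            "k_folds": config.k_folds,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages and write artifacts plus a run manifest.

    Writes ``measures.csv``, ``effects.csv``, ``detection_summary.csv``,
    ``report_<criterion>.csv`` and ``manifest.json`` under ``out_dir``.
    Reruns with the same config produce identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.study.seed,
        "swaylab_version": __version__,
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s started", name)

        def done(**counts):
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3), **counts}
            log.info("stage %s finished in %.2fs %s", name, dt, counts)

        return done

    done = stage("simulate")
    dataset = simulate_study(config.study)
    done(trials=len(dataset))

    done = stage("measures")
    opts = MeasureOptions(cutoff=config.cutoff_acc, filter_order=config.filter_order)
    measures = compute_study_measures(dataset, opts=opts)
    measures.to_csv(out / "measures.csv", index=False)
    done(rows=len(measures), sensors=len(config.study.sensor_set))

    done = stage("effects")
    effects_long, detection = run_effects_battery(measures, alpha=config.alpha)
    effects_long.to_csv(out / "effects.csv", index=False)
    detection.to_csv(out / "detection_summary.csv")
    done(anova_rows=len(effects_long))

    done = stage("classify")
    grid = ClassificationGrid(
        dataset,
        sensor_configs=config.sensor_configs,
        feature_sets=config.feature_sets,
        classifiers=config.classifiers,
        criterion=config.criterion,
        k=config.k_folds,
    )
    report = grid.fit(seed=config.study.seed)
    from .io import write_report

    write_report(report, out / f"report_{config.criterion}.csv")
    done(cells=report.accuracy.size)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
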