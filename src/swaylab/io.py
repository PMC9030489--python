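"""Study directory format: plain CSV signals plus a YAML config.

Layout written by :func:`write_study`::

    out/
      study.yaml                      # StudyConfig, field-for-field
      metadata.csv                    # subject, posture, surface, load,
                                      # repetition, pps
      trials/
        S001_P1_flat_0kg_r1_pelvis.csv   # time,AP,ML,IS (m/s^2)
        ...
        S001_P1_flat_0kg_r1_COP.csv      # time,AP,ML (mm)

Floats are serialised with 17 significant digits so a write/read round
trip reproduces every signal bit-for-bit. The same dialect serves as
the entry point for real exported IMU data.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig, load_study_config, save_study_config
from .design import Condition
from .simulate import StudyDataset, TrialRecording

_FLOAT_FMT = "%.17g"
_META_COLUMNS = ["subject", "posture", "surface", "load", "repetition", "pps"]


def _trial_stem(t: TrialRecording) -> str:
    return f"S{t.subject_id:03d}_{t.condition.label()}_r{t.repetition}"


def write_study(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write a study to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    save_study_config(dataset.config, out / "study.yaml")
    dataset.metadata().to_csv(
        out / "metadata.csv", index=False, float_format=_FLOAT_FMT
    )
    for t in dataset.trials:
        stem = _trial_stem(t)
        t_acc = np.arange(t.acc[next(iter(t.acc))].shape[0]) / t.acc_rate
        for sensor, arr in t.acc.items():
            df = pd.DataFrame(
                {"time": t_acc, "AP": arr[:, 0], "ML": arr[:, 1], "IS": arr[:, 2]}
            )
            df.to_csv(
                trials_dir / f"{stem}_{sensor}.csv",
                index=False,
                float_format=_FLOAT_FMT,
            )
        t_cop = np.arange(t.cop.shape[0]) / t.cop_rate
        pd.DataFrame({"time": t_cop, "AP": t.cop[:, 0], "ML": t.cop[:, 1]}).to_csv(
            trials_dir / f"{stem}_COP.csv", index=False, float_format=_FLOAT_FMT
        )
    return out


class StudyFormatError(ValueError):
    """Malformed or incomplete study directory."""


def _read_signal(path: Path, columns: list[str]) -> np.ndarray:
    if not path.exists():
        raise StudyFormatError(f"missing signal file {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # parse error with file context
        raise StudyFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StudyFormatError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in columns and c != "time"]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    return df[columns].to_numpy(dtype=float)


def read_study(in_dir: str | Path, config: StudyConfig | None = None) -> StudyDataset:
    """Read a study directory written by :func:`write_study`."""
    src = Path(in_dir)
    if config is None:
        cfg_path = src / "study.yaml"
        if not cfg_path.exists():
            raise StudyFormatError(f"missing {cfg_path}")
        config = load_study_config(cfg_path)
    meta_path = src / "metadata.csv"
    if not meta_path.exists():
        raise StudyFormatError(f"missing {meta_path}")
    meta = pd.read_csv(meta_path, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise StudyFormatError(f"{meta_path}: missing columns {missing}")
    trials: list[TrialRecording] = []
    for row in meta.itertuples(index=False):
        cond = Condition(row.posture, row.surface, row.load)
        stem = f"S{int(row.subject):03d}_{cond.label()}_r{int(row.repetition)}"
        acc = {
            sensor: _read_signal(
                src / "trials" / f"{stem}_{sensor}.csv", ["AP", "ML", "IS"]
            )
            for sensor in config.sensor_set
        }
        cop = _read_signal(src / "trials" / f"{stem}_COP.csv", ["AP", "ML"])
        trials.append(
            TrialRecording(
                subject_id=int(row.subject),
                condition=cond,
                repetition=int(row.repetition),
                acc=acc,
                cop=cop,
                pps=float(row.pps),
                acc_rate=config.acc_rate,
                cop_rate=config.cop_rate,
            )
        )
    return StudyDataset(trials=trials, config=config)


def write_report(report, out_path: str | Path) -> None:
    """Write a classification report grid (with summary rows) as CSV."""
    df = report.with_summary_rows()
    df.columns = [f"{sc}_{fs}" for sc, fs in df.columns]
    df.round(1).to_csv(out_path, index_label="classifier")
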