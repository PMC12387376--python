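"""File formats: npz containers for signals, CSV tables, JSON reports.

One ``.npz`` file per subject holds the raw channels, sampling rate,
wall-clock start, optional ground-truth breath annotations and artifact
intervals.  Breath series, features and covariates travel as CSV; configs and
the statistical report as JSON.
"""

from __future__ import annotations

import json
import zipfile
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GROUND_TRUTH_COLUMNS, ClinicalCovariates, RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_covariates",
    "read_covariates",
    "write_report",
    "read_report",
]

_REQUIRED_KEYS = ("chest", "abdomen", "accel", "fs", "start_clock")


def write_recording(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording to an npz container (lossless round-trip)."""
    path = Path(path)
    payload: dict[str, np.ndarray] = {
        "chest": recording.chest,
        "abdomen": recording.abdomen,
        "accel": recording.accel,
        "fs": np.asarray(recording.fs, dtype=float),
        "start_clock": np.asarray(recording.start_clock.isoformat()),
    }
    if recording.ground_truth is not None:
        for col in GROUND_TRUTH_COLUMNS:
            payload[f"gt_{col}"] = recording.ground_truth[col].to_numpy(dtype=float)
    if recording.artifacts:
        payload["artifacts"] = np.asarray(recording.artifacts, dtype=float)
    np.savez(path, **payload)
    return path


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording container, naming any missing field."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as data:
            for key in _REQUIRED_KEYS:
                if key not in data:
                    raise KeyError(
                        f"recording container {path.name} is missing field {key!r}"
                    )
            gt = None
            gt_keys = [k for k in data.files if k.startswith("gt_")]
            if gt_keys:
                gt = pd.DataFrame(
                    {col: data[f"gt_{col}"] for col in GROUND_TRUTH_COLUMNS}
                )
            artifacts = (
                [tuple(row) for row in data["artifacts"]]
                if "artifacts" in data
                else []
            )
            return RawRecording(
                start_clock=datetime.fromisoformat(str(data["start_clock"])),
                fs=float(data["fs"]),
                chest=data["chest"],
                abdomen=data["abdomen"],
                accel=data["accel"],
                ground_truth=gt,
                artifacts=artifacts,
            )
    except (OSError, ValueError, EOFError, zipfile.BadZipFile) as exc:
        raise ValueError(
            f"could not parse recording container {path}: {exc}"
        ) from exc


def write_covariates(
    covariates: list[ClinicalCovariates] | pd.DataFrame, path: str | Path
) -> Path:
    from .synthetic import covariates_frame

    path = Path(path)
    df = (
        covariates
        if isinstance(covariates, pd.DataFrame)
        else covariates_frame(covariates)
    )
    df.to_csv(path)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    required = {"age", "sex", "dbp", "sbp", "nyha", "log_ntprobnp", "pc_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariates table missing columns: {sorted(missing)}")
    if "male" not in df.columns:
        df["male"] = (df["sex"] == "male").astype(int)
    if "nyha_iv" not in df.columns:
        df["nyha_iv"] = (df["nyha"] == "IV").astype(int)
    return df


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
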