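"""Trial/calibration file I/O and result serialization.

Trials travel as tidy CSV (one file per trial) with columns
``t, angle_x_deg, angle_y_deg, emg_ecr, emg_ecu, emg_fcu, emg_fcr`` and a
YAML sidecar (same stem, ``.yaml``) carrying the sampling rate, task,
direction and EMG kind.  Calibrations use the same CSV schema with
``torque_nm`` metadata.  Cohort ratio tables are tidy CSV with columns
``subject_id, group, task, ratio`` (clinical columns are carried as
opaque metadata).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal import CalibrationRecording, TrialRecording

__all__ = [
    "TRIAL_COLUMNS",
    "read_trial",
    "read_trials",
    "write_trial",
    "read_calibration",
    "write_calibration",
    "load_reference_cohort",
    "write_json",
    "config_hash",
]

TRIAL_COLUMNS = [
    "t", "angle_x_deg", "angle_y_deg", "emg_ecr", "emg_ecu", "emg_fcu", "emg_fcr",
]
_EMG_COLS = TRIAL_COLUMNS[3:]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[TRIAL_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # 1-based, after header
        raise ValueError(f"{path}: malformed rows at lines {lines[:10]}")
    dt = np.diff(df["t"].to_numpy())
    if len(dt) and np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise ValueError(f"{path}: time not strictly increasing at line {line}")
    return df


def read_trial(path) -> TrialRecording:
    """Read one trial CSV and its YAML sidecar into a TrialRecording."""
    path = Path(path)
    df = _read_table(path)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh) or {}
    fs = float(meta.pop("fs"))
    task = meta.pop("task")
    direction = meta.pop("direction", None)
    kind = meta.pop("emg_kind", "raw")
    target = None
    if {"target_x_deg", "target_y_deg"}.issubset(df.columns):
        target = df[["target_x_deg", "target_y_deg"]].to_numpy()
    return TrialRecording(
        time=df["t"].to_numpy(),
        angle_x_deg=df["angle_x_deg"].to_numpy(),
        angle_y_deg=df["angle_y_deg"].to_numpy(),
        emg=df[_EMG_COLS].to_numpy(),
        fs=fs,
        task=task,
        direction=direction,
        target_path=target,
        emg_kind=kind,
        meta=meta,
    )


def read_trials(paths) -> list:
    """Read many trials; ``paths`` is an iterable, directory, or manifest.

    A directory loads every ``*.csv`` inside (sidecars required); a
    ``.txt``/``.lst`` manifest lists one trial CSV path per line.
    """
    paths = Path(paths) if isinstance(paths, (str, Path)) else paths
    if isinstance(paths, Path):
        if paths.is_dir():
            paths = sorted(paths.glob("*.csv"))
        elif paths.suffix in (".txt", ".lst"):
            base = paths.parent
            paths = [base / line.strip() for line in paths.read_text().splitlines() if line.strip()]
        else:
            paths = [paths]
    return [read_trial(p) for p in paths]


def write_trial(path, trial: TrialRecording) -> Path:
    """Write a trial as CSV + YAML sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": trial.time,
            "angle_x_deg": trial.angle_x_deg,
            "angle_y_deg": trial.angle_y_deg,
            **{c: trial.emg[:, i] for i, c in enumerate(_EMG_COLS)},
        }
    )
    if trial.target_path is not None:
        df["target_x_deg"] = trial.target_path[:, 0]
        df["target_y_deg"] = trial.target_path[:, 1]
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": trial.fs,
        "task": trial.task,
        "emg_kind": trial.emg_kind,
        **{k: v for k, v in trial.meta.items()},
    }
    if trial.direction is not None:
        meta["direction"] = trial.direction
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(_plain(meta), fh, sort_keys=False)
    return path


def write_calibration(path, calib: CalibrationRecording) -> Path:
    path = Path(path)
    n = len(calib.emg)
    df = pd.DataFrame(
        {
            "t": np.arange(n) / calib.fs,
            "angle_x_deg": np.zeros(n),
            "angle_y_deg": np.zeros(n),
            **{c: calib.emg[:, i] for i, c in enumerate(_EMG_COLS)},
            **{f"rest_{c}": calib.central_rest[:, i] for i, c in enumerate(_EMG_COLS)},
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(
            {
                "fs": float(calib.fs),
                "torque_nm": float(calib.torque_level),
                "emg_kind": calib.emg_kind,
            },
            fh,
        )
    return path


def read_calibration(path) -> CalibrationRecording:
    path = Path(path)
    df = pd.read_csv(path)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    rest_cols = [f"rest_{c}" for c in _EMG_COLS]
    return CalibrationRecording(
        emg=df[_EMG_COLS].to_numpy(),
        central_rest=df[rest_cols].to_numpy() if set(rest_cols).issubset(df.columns)
        else df[_EMG_COLS].to_numpy(),
        fs=float(meta["fs"]),
        torque_level=float(meta.get("torque_nm", 0.78)),
        emg_kind=meta.get("emg_kind", "raw"),
    )


def load_reference_cohort() -> pd.DataFrame:
    """The packaged per-subject ratio table (10 controls, 19 patients)."""
    ref = resources.files("wristid.data").joinpath("cohort_ratios.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON dumping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json(path, payload: dict, seed: int | None = None) -> Path:
    """Dump results JSON, stamping the package version, seed and a hash."""
    from . import __version__

    path = Path(path)
    body = _plain(payload)
    body.setdefault("_meta", {})
    body["_meta"].update({"package": "wristid", "version": __version__})
    if seed is not None:
        body["_meta"]["seed"] = int(seed)
    body["_meta"]["config_hash"] = config_hash(body)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2)
    return path


def config_hash(obj) -> str:
    blob = json.dumps(_plain(obj), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
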