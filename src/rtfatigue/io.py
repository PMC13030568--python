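"""Plain-CSV interchange formats with load-time invariant checks.

Dialects (all with a header row; times in seconds, floats):

* gaze:     ``t_s, x_deg, y_deg, pupil_mm[, valid]``
* ECG:      ``t_s, mv``
* sessions: ``subject_id, scenario_id, scenario_type, start_s, end_s, sp7_post``
* features: metadata columns + the 12 named feature columns; written with a
  ``# rtfatigue-schema`` / ``# config`` comment preamble carrying the schema
  version and producing-config hash.

Sampling rates are inferred from the time base and validated against the
nominal rates (gaze 100 Hz, ECG 512 Hz, within 1%).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cardiac import ECGTrace
from .dataset import FEATURE_NAMES
from .ocular import GazeStream

__all__ = [
    "read_gaze",
    "write_gaze",
    "read_ecg",
    "write_ecg",
    "read_sessions",
    "write_sessions",
    "read_features",
    "write_features",
]

GAZE_NOMINAL_HZ = 100.0
ECG_NOMINAL_HZ = 512.0
FEATURE_SCHEMA = "rtfatigue-feature-table-v1"

_SESSION_COLS = ["subject_id", "scenario_id", "scenario_type", "start_s", "end_s", "sp7_post"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _check_rate(t: np.ndarray, nominal: float, path) -> None:
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ValueError(f"{path}: time not strictly increasing at data row {bad[0] + 1}")
    rate = 1.0 / float(np.median(dt))
    if abs(rate - nominal) > 0.01 * nominal:
        raise ValueError(
            f"{path}: inferred rate {rate:.1f} Hz outside 1% of nominal {nominal:.0f} Hz"
        )


def read_gaze(path) -> GazeStream:
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "x_deg", "y_deg", "pupil_mm"], path)
    t = df["t_s"].to_numpy(float)
    _check_rate(t, GAZE_NOMINAL_HZ, path)
    valid = (
        df["valid"].astype(bool).to_numpy()
        if "valid" in df.columns
        else df["pupil_mm"].to_numpy(float) > 0
    )
    return GazeStream(
        t, df["x_deg"].to_numpy(float), df["y_deg"].to_numpy(float),
        df["pupil_mm"].to_numpy(float), valid,
    )


def write_gaze(stream: GazeStream, path) -> None:
    pd.DataFrame(
        {
            "t_s": stream.t,
            "x_deg": stream.x,
            "y_deg": stream.y,
            "pupil_mm": stream.pupil,
            "valid": stream.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_ecg(path) -> ECGTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "mv"], path)
    t = df["t_s"].to_numpy(float)
    _check_rate(t, ECG_NOMINAL_HZ, path)
    return ECGTrace(t, df["mv"].to_numpy(float))


def write_ecg(trace: ECGTrace, path) -> None:
    pd.DataFrame({"t_s": trace.t, "mv": trace.v}).to_csv(path, index=False)


def read_sessions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _SESSION_COLS, path)
    bad = df.index[(df["sp7_post"] < 1) | (df["sp7_post"] > 7)]
    if len(bad):
        raise ValueError(f"{path}: sp7_post outside 1-7 at data row {bad[0] + 1}")
    bad = df.index[df["end_s"] <= df["start_s"]]
    if len(bad):
        raise ValueError(f"{path}: end_s <= start_s at data row {bad[0] + 1}")
    for subject, grp in df.groupby("subject_id"):
        g = grp.sort_values("start_s")
        if (g["start_s"].to_numpy()[1:] < g["end_s"].to_numpy()[:-1]).any():
            raise ValueError(f"{path}: overlapping scenarios for subject {subject}")
    return df


def write_sessions(session: pd.DataFrame, path) -> None:
    session[[c for c in session.columns if c in _SESSION_COLS + ["regime"]]].to_csv(
        path, index=False
    )


def write_features(features: pd.DataFrame, path, config_hash: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FEATURE_SCHEMA}\n# config: {config_hash}\n")
        features.to_csv(fh, index=False)


def read_features(path) -> tuple[pd.DataFrame, dict]:
    """Feature table plus its schema/config metadata; schema mismatches raise."""
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("config:"):
                meta["config_hash"] = body.split(":", 1)[1].strip()
            else:
                meta["schema"] = body
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if meta.get("schema") != FEATURE_SCHEMA:
        raise ValueError(f"{path}: unrecognised feature-table schema {meta.get('schema')!r}")
    _require_columns(df, ["subject_id", "scenario_id", "window_index", "sp7", "label"], path)
    _require_columns(df, FEATURE_NAMES, path)
    return df, meta


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
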