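"""Readers and writers for the instrument CSV dialects.

Three inputs: a pose table in the DeepLabCut CSV dialect (three header rows
scorer/bodyparts/coords, x,y,likelihood per marker, 120 fps), an
optical-flow sensor log (t, dx1, dy1, dx2, dy2 at 50 Hz), and a multichannel
EMG log (t plus one column per channel at 5000 Hz).  Writers emit exactly
the dialect the readers consume; ground truth travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_MARKERS",
    "PoseTable",
    "read_pose_table",
    "write_pose_table",
    "read_sensor_log",
    "write_sensor_log",
    "read_emg_log",
    "write_emg_log",
    "read_truth_sidecar",
    "write_truth_sidecar",
]

REQUIRED_MARKERS = (
    "Head", "Pro", "Meso", "Meta",
    "LF1", "LF2", "LM1", "LM2", "LH1", "LH2",
    "RF1", "RF2", "RM1", "RM2", "RH1", "RH2",
    "Bar", "Axis", "Fix", "LED1", "LED2",
)

POSE_FPS = 120.0
SENSOR_RATE = 50.0
EMG_RATE = 5000.0
RATE_TOL = 0.01  # 1%


@dataclass
class PoseTable:
    """Likelihood-masked marker table.

    ``data`` has column MultiIndex (bodypart, coord); frames whose
    likelihood fell below the floor have x,y set to NaN.  ``n_masked`` maps
    marker -> number of masked frames.
    """

    data: pd.DataFrame
    fps: float
    n_masked: dict


def read_pose_table(
    path, likelihood_floor: float = 0.9, fps: float = POSE_FPS
) -> PoseTable:
    """Read a pose-estimation CSV (scorer/bodyparts/coords header dialect).

    Raises a ValueError naming any missing required marker.  Frames below
    the likelihood floor are masked to NaN and counted per marker.
    """
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = df.columns.droplevel(0)  # drop scorer
    markers = set(df.columns.get_level_values(0))
    missing = [m for m in REQUIRED_MARKERS if m not in markers]
    if missing:
        raise ValueError(f"pose table is missing required markers: {', '.join(missing)}")
    n_masked = {}
    for m in REQUIRED_MARKERS:
        like = df[(m, "likelihood")].to_numpy(float)
        bad = like < likelihood_floor
        n_masked[m] = int(bad.sum())
        if bad.any():
            df.loc[bad, (m, "x")] = np.nan
            df.loc[bad, (m, "y")] = np.nan
    return PoseTable(data=df, fps=fps, n_masked=n_masked)


def write_pose_table(table: pd.DataFrame, path) -> None:
    """Write a marker table with the three-row header dialect."""
    if table.columns.nlevels != 3:
        raise ValueError("pose table requires (scorer, bodyparts, coords) columns")
    table.to_csv(path, index=True)


def _validate_log(df: pd.DataFrame, expected_rate: float, what: str):
    t = df["t"].to_numpy(float)
    dt = np.diff(t)
    if t.size > 1 and not np.all(dt > 0):
        raise ValueError(f"{what}: time column is not strictly increasing")
    if t.size > 2:
        rate = 1.0 / np.median(dt)
        if abs(rate - expected_rate) > RATE_TOL * expected_rate:
            raise ValueError(
                f"{what}: sampling rate {rate:.2f} Hz outside "
                f"{expected_rate} Hz +/- {RATE_TOL:.0%}"
            )
    # gap report: spacings larger than 3 nominal samples
    gaps = np.flatnonzero(dt > 3.0 / expected_rate)
    return [(int(i), float(dt[i])) for i in gaps]


def read_sensor_log(path) -> tuple[pd.DataFrame, list]:
    """Read an optical-flow sensor log; returns (frame, gap report)."""
    df = pd.read_csv(path)
    required = {"t", "dx1", "dy1", "dx2", "dy2"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"sensor log is missing columns: {', '.join(sorted(required - set(df.columns)))}"
        )
    gaps = _validate_log(df, SENSOR_RATE, "sensor log")
    return df, gaps


def write_sensor_log(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_emg_log(path) -> tuple[dict, list]:
    """Read a multichannel EMG log; returns ({muscle: EMGRecord}, gap report)."""
    from .emg import EMGRecord

    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError("EMG log is missing the 't' column")
    if df.shape[1] < 2:
        raise ValueError("EMG log has no channel columns")
    gaps = _validate_log(df, EMG_RATE, "EMG log")
    t = df["t"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 2 else EMG_RATE
    records = {
        col: EMGRecord(muscle=col, fs=fs, samples=df[col].to_numpy(float), t0=float(t[0]))
        for col in df.columns
        if col != "t"
    }
    return records, gaps


def write_emg_log(records: dict, path) -> None:
    """Write EMG channels sharing one clock to a single CSV."""
    first = next(iter(records.values()))
    n = first.samples.size
    t = first.t0 + np.arange(n) / first.fs
    out = {"t": t}
    for name, rec in records.items():
        if rec.samples.size != n:
            raise ValueError("all EMG channels must share a length")
        out[name] = rec.samples
    pd.DataFrame(out).to_csv(path, index=False)


def write_truth_sidecar(truth: dict, path) -> None:
    """Ground-truth JSON sidecar next to a synthetic bundle."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=1, default=_default, sort_keys=True))


def read_truth_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
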