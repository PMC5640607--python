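"""Columnar text formats and run manifests.

All tables are plain CSV with a header row; times in ms, positions and
headings in degrees. Columns are matched by name, so column order is
free, and a missing column raises a SchemaError naming it. Manifests are
YAML key-value files recording the seed and parameters of a run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eye_events import EyeTrace

EYE_TRACE_COLUMNS = ["time_ms", "x_deg", "y_deg"]
SPIKE_COLUMNS = ["neuron_id", "time_ms"]
TRIAL_COLUMNS = ["subject", "condition", "onset_ms", "true_heading_deg",
                 "reported_heading_deg", "alpha_deg", "head_deg"]


class SchemaError(ValueError):
    """A table is missing a required column."""


def _check_schema(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_table(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, columns, path)
    return df[list(columns) + [c for c in df.columns if c not in columns]]


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_eye_trace(trace: EyeTrace, path) -> None:
    write_table(pd.DataFrame({"time_ms": trace.time_ms,
                              "x_deg": trace.horiz_deg,
                              "y_deg": trace.vert_deg}), path)


def read_eye_trace(path, sampling_rate_hz: float | None = None) -> EyeTrace:
    df = read_table(path, EYE_TRACE_COLUMNS)
    t = df["time_ms"].to_numpy(dtype=float)
    if sampling_rate_hz is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from "
                             "fewer than 2 samples")
        sampling_rate_hz = 1000.0 / float(np.median(np.diff(t)))
    return EyeTrace(time_ms=t, horiz_deg=df["x_deg"].to_numpy(dtype=float),
                    vert_deg=df["y_deg"].to_numpy(dtype=float),
                    sampling_rate_hz=sampling_rate_hz)


def write_spikes(trains, path) -> None:
    """One row per spike: neuron_id, time_ms. ``trains`` is a sequence of arrays."""
    ids = np.concatenate([np.full(len(tr), i, dtype=int)
                          for i, tr in enumerate(trains)]) if trains else np.array([], int)
    times = np.concatenate([np.asarray(tr, float) for tr in trains]) if trains else np.array([])
    write_table(pd.DataFrame({"neuron_id": ids, "time_ms": times}), path)


def read_spikes(path) -> list[np.ndarray]:
    df = read_table(path, SPIKE_COLUMNS)
    if df.empty:
        return []
    n = int(df["neuron_id"].max()) + 1
    return [np.sort(df.loc[df["neuron_id"] == i, "time_ms"].to_numpy(dtype=float))
            for i in range(n)]


def write_trials(trials: pd.DataFrame, path) -> None:
    _check_schema(trials, TRIAL_COLUMNS, path)
    write_table(trials, path)


def read_trials(path) -> pd.DataFrame:
    return read_table(path, TRIAL_COLUMNS)


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
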