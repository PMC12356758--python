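"""Canonical CSV/JSON formats and validation.

One CSV dialect throughout: UTF-8, comma-separated, '.' decimal, header
required, floats written with 17 significant digits so numeric round-trips
are exact.  Tasks are encoded as the strings "perceptual" and "value".
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TRACE_COLUMNS",
    "SEQUENCE_COLUMNS",
    "read_traces",
    "write_traces",
    "read_sequences",
    "write_sequences",
    "read_config",
    "write_config",
    "config_hash",
]

TRACE_COLUMNS = ["subject", "task", "block", "trial", "pair", "t_seconds", "y"]
SEQUENCE_COLUMNS = ["block", "trial", "pair", "ie_level", "ie_rescaled",
                    "simple_ae"]
FLOAT_FORMAT = "%.17g"
_Y_TOL = 1e-12


def _read_csv(path, columns):
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed CSV {path}: {e}") from e
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[columns]


def read_traces(path) -> pd.DataFrame:
    """Read and validate a slider-trace table.

    Checks: known task labels, y within [-1, +1], strictly increasing sample
    times and nondecreasing pair indices within each trial.  An empty table
    round-trips to an empty frame with a warning.
    """
    df = _read_csv(path, TRACE_COLUMNS)
    if df.empty:
        warnings.warn(f"{path}: no slider samples", stacklevel=2)
        return df
    bad_task = ~df["task"].isin(["perceptual", "value"])
    if bad_task.any():
        row = int(df.index[bad_task][0])
        raise ValueError(
            f"{path} row {row + 2}: unknown task {df['task'][row]!r}"
        )
    out_of_range = df["y"].abs() > 1.0 + _Y_TOL
    if out_of_range.any():
        row = int(df.index[out_of_range][0])
        raise ValueError(
            f"{path} row {row + 2}: slider position y={df['y'][row]} "
            "outside [-1, +1]"
        )
    for key, g in df.groupby(["subject", "task", "block", "trial"]):
        t = g["t_seconds"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: non-increasing sample times in "
                             f"(subject, task, block, trial)={key}")
        if np.any(np.diff(g["pair"].to_numpy()) < 0):
            raise ValueError(f"{path}: decreasing pair index in "
                             f"(subject, task, block, trial)={key}")
    return df


def write_traces(traces: pd.DataFrame, path):
    traces[TRACE_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sequences(path) -> pd.DataFrame:
    df = _read_csv(path, SEQUENCE_COLUMNS)
    if df.duplicated(["block", "trial", "pair"]).any():
        raise ValueError(f"{path}: duplicated (block, trial, pair) rows")
    return df


def write_sequences(sequences: pd.DataFrame, path):
    sequences[SEQUENCE_COLUMNS].to_csv(path, index=False,
                                       float_format=FLOAT_FORMAT)


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_config(config: dict, path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()
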