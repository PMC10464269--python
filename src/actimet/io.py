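"""Delimited-text I/O for epoch streams, cohort tables and configs.

All on-disk formats are plain text: epoch streams as CSV with one row per
5-second epoch (``participant_id,timestamp,label``, ISO-8601 timestamps),
cohort and result tables as CSV with stable column names, and run
configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .accel import EpochStream

__all__ = [
    "write_epoch_streams",
    "read_epoch_streams",
    "write_table",
    "read_table",
    "load_yaml",
    "dump_yaml",
]

_FLOAT_FORMAT = "%.6g"


def write_epoch_streams(streams: dict[str, EpochStream], path: str | Path) -> Path:
    """Write epoch streams to one CSV (one row per 5-s epoch)."""
    path = Path(path)
    frames = [streams[pid].to_frame() for pid in sorted(streams)]
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)
    return path


def read_epoch_streams(path: str | Path) -> dict[str, EpochStream]:
    """Read an epoch-stream CSV back into per-participant streams."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    return {
        pid: EpochStream.from_frame(sub.reset_index(drop=True))
        for pid, sub in df.groupby("participant_id", sort=True)
    }


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
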