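"""Readers and writers for the pipeline's tabular formats.

Event tables, ground truth and reports travel as plain CSV; traces as a
columnar table (CSV, or HDF5 when h5py is available) with ``time_s``
first and one column per channel, the sampling rate recorded in a
``# sampling_rate_hz`` header line (CSV) or attribute (HDF5).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import TraceRecord

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_trace",
    "write_trace",
    "read_config",
    "mean_ct",
]

REQUIRED_EVENT_COLUMNS = ("droplet_id", "duration_samples")


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Load and validate an event-table CSV.

    Requires ``droplet_id`` and ``duration_samples`` plus at least one
    ``mean_<channel>`` column; raises naming the first missing column,
    and rejects duplicate droplet ids and non-numeric fluorescence.
    """
    events = pd.read_csv(path)
    for col in REQUIRED_EVENT_COLUMNS:
        if col not in events.columns:
            raise ValueError(f"event table {path} missing required column {col!r}")
    mean_cols = [c for c in events.columns if c.startswith("mean_")]
    if not mean_cols:
        raise ValueError(f"event table {path} has no mean_<channel> column")
    for col in mean_cols:
        if not np.issubdtype(events[col].dtype, np.number):
            raise ValueError(f"non-numeric fluorescence in column {col!r}")
    if events["droplet_id"].duplicated().any():
        dup = events.loc[events["droplet_id"].duplicated(), "droplet_id"].iloc[0]
        raise ValueError(f"duplicate droplet_id {dup!r}")
    return events


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def write_trace(trace: TraceRecord, path: str | Path) -> None:
    """Write a trace as CSV (``.csv``) or HDF5 (``.h5``/``.hdf5``)."""
    path = Path(path)
    t = np.arange(trace.n_samples) / trace.sampling_rate
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("samples", data=trace.samples)
            ds.attrs["sampling_rate_hz"] = trace.sampling_rate
            ds.attrs["channel_names"] = trace.channel_names
            ds.attrs["detection_channel"] = trace.detection_channel
        return
    df = pd.DataFrame({"time_s": t})
    for j, ch in enumerate(trace.channel_names):
        df[ch] = trace.samples[:, j]
    with open(path, "w") as f:
        f.write(f"# sampling_rate_hz={trace.sampling_rate}\n")
        f.write(f"# detection_channel={trace.detection_channel}\n")
        df.to_csv(f, index=False)


def read_trace(path: str | Path, detection_channel: str | None = None) -> TraceRecord:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["samples"]
            channels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in ds.attrs["channel_names"]
            ]
            det = detection_channel or str(ds.attrs["detection_channel"])
            return TraceRecord(float(ds.attrs["sampling_rate_hz"]), channels, ds[...], det)
    header: dict[str, str] = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        df = pd.read_csv(f)
    if "sampling_rate_hz" not in header:
        raise ValueError(f"trace {path} lacks a '# sampling_rate_hz=' header")
    channels = [c for c in df.columns if c != "time_s"]
    det = detection_channel or header.get("detection_channel", channels[0])
    return TraceRecord(
        float(header["sampling_rate_hz"]), channels, df[channels].to_numpy(), det
    )


def read_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration (one section per stage)."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of sections")
    return cfg


def mean_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Cts per (sample, gene, condition).

    Input columns: ``sample``, ``gene``, ``condition``, ``ct`` (extra
    columns are ignored). Returns one mean Ct per group.
    """
    for col in ("sample", "gene", "condition", "ct"):
        if col not in ct_table.columns:
            raise ValueError(f"Ct table missing required column {col!r}")
    return (
        ct_table.groupby(["sample", "gene", "condition"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "mean_ct"})
    )
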