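"""File I/O: signals (WAV / CSV), event and interval tables, YAML config.

Conventions: times persisted in seconds for file-level columns, interval
columns in milliseconds; CSV is UTF-8, comma-separated, ``.`` decimal, header
row mandatory; missing values are empty cells.
"""
from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .events import EVENT_NAMES, ValveEventSet
from .intervals import GroupStatsTable
from .records import SignalRecord

__all__ = [
    "read_signal",
    "write_wav",
    "read_r_peaks",
    "write_events_csv",
    "read_events_csv",
    "write_intervals_csv",
    "read_intervals_csv",
    "write_stats_report",
    "load_config",
]

_EVENT_COLS = [f"t_{e}_ms" for e in EVENT_NAMES]


def read_signal(path, fs: float | None = None, fmt: str | None = None) -> SignalRecord:
    """Read a mono waveform from a 16-bit PCM WAV or a CSV file.

    CSV accepts two layouts: ``time_s,value`` (the rate is inferred from the
    median time step and must be uniform within 1%) or a single ``value``
    column with the rate supplied via ``fs``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "wav" if path.suffix.lower() == ".wav" else "csv"
    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("mono required")
        if data.dtype == np.int16:
            samples = data.astype(np.float64) / 32768.0
        elif data.dtype == np.int32:
            samples = data.astype(np.float64) / 2147483648.0
        else:
            samples = data.astype(np.float64)
        return SignalRecord(samples, float(rate), label=path.name)
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time_s" in cols and "value" in cols:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0 or np.max(np.abs(dt - med)) > 0.01 * med:
            raise ValueError("non-uniform CSV time axis")
        return SignalRecord(df["value"].to_numpy(dtype=float), 1.0 / med, label=path.name, t0=float(t[0]))
    if len(cols) == 1:
        if fs is None:
            raise ValueError("single-column CSV needs an explicit sampling rate")
        return SignalRecord(df[cols[0]].to_numpy(dtype=float), fs, label=path.name)
    raise ValueError("CSV must have columns time_s,value or a single value column")


def write_wav(path, record: SignalRecord) -> None:
    """Write as 16-bit PCM mono, clipping to [-1, 1)."""
    x = np.clip(record.samples, -1.0, 32767.0 / 32768.0)
    wavfile.write(path, int(round(record.fs)), (x * 32768.0).astype(np.int16))


def read_r_peaks(path) -> np.ndarray:
    """R-peak annotation CSV: single column ``r_time_s`` of times in seconds."""
    df = pd.read_csv(path)
    col = df.columns[0]
    t = df[col].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("r-peak times must be strictly increasing")
    return t


def write_events_csv(
    path,
    events: list[ValveEventSet],
    anchor_times_s: np.ndarray,
    rr_ms: list[float],
) -> None:
    rows = []
    for ev, rr in zip(events, rr_ms):
        row = dict(
            beat_index=ev.beat_index,
            anchor_time_s=float(anchor_times_s[ev.beat_index])
            if ev.beat_index < len(anchor_times_s)
            else math.nan,
            rr_ms=rr,
        )
        for e in EVENT_NAMES:
            row[f"t_{e}_ms"] = ev.time(e)
        row["flags"] = ";".join(sorted(ev.quality_flags)) if ev.quality_flags else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"beat_index", "rr_ms", *_EVENT_COLS}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    return df


def write_intervals_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_intervals_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_stats_report(base_path, table: GroupStatsTable) -> None:
    """Write the group report as CSVs (rounded for reading) plus full-precision JSON."""
    base = Path(base_path)
    base.mkdir(parents=True, exist_ok=True)
    table.summary.round(1).to_csv(base / "group_summary.csv", index=False)
    table.kruskal.to_csv(base / "kruskal_wallis.csv", index=False)
    table.pairwise.to_csv(base / "pairwise_mannwhitney.csv", index=False)
    table.correlations.to_csv(base / "age_correlations.csv", index=False)
    payload = {
        "summary": table.summary.to_dict(orient="records"),
        "kruskal": table.kruskal.to_dict(orient="records"),
        "pairwise": table.pairwise.to_dict(orient="records"),
        "correlations": table.correlations.to_dict(orient="records"),
    }
    (base / "stats_report.json").write_text(json.dumps(payload, indent=2, allow_nan=True))


def load_config(path) -> dict:
    """Load the YAML run configuration (blocks: swd, events, stats, synthetic)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
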