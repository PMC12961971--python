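"""CSV/JSON readers and writers for the device data streams.

Formats:

* dIEA CSV — ``timestamp,count`` (ISO-8601, non-negative integers);
* visits CSV — ``visit_date``;
* events CSV — ``timestamp,type,has_stim,stim_offsets_s`` with offsets as
  semicolon-separated seconds (empty for none);
* ground truth JSON; EDF clips named by catalog row id (see
  :mod:`multidien.edf`).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import DIEASeries, EventCatalog


def write_diea_csv(path, series: DIEASeries) -> None:
    pd.DataFrame(
        {"timestamp": series.timestamps, "count": series.counts}
    ).to_csv(path, index=False)


def read_diea_csv(path) -> tuple[pd.DatetimeIndex, np.ndarray]:
    df = pd.read_csv(path)
    _require(df, ("timestamp", "count"), path)
    try:
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header
        raise ValueError(f"{path}:{line}: invalid count {df['count'][bad.idxmax()]!r}")
    return ts, counts.to_numpy(int)


def write_visits_csv(path, visit_dates) -> None:
    pd.DataFrame({"visit_date": pd.DatetimeIndex(visit_dates)}).to_csv(
        path, index=False
    )


def read_visits_csv(path) -> pd.DatetimeIndex:
    df = pd.read_csv(path)
    _require(df, ("visit_date",), path)
    return pd.DatetimeIndex(pd.to_datetime(df["visit_date"]))


def write_events_csv(path, catalog: EventCatalog) -> None:
    df = catalog.frame.copy()
    df["stim_offsets_s"] = [
        ";".join(f"{o:g}" for o in offs) for offs in df["stim_offsets_s"]
    ]
    df.to_csv(path, index=False)


def read_events_csv(path) -> EventCatalog:
    df = pd.read_csv(path, dtype={"stim_offsets_s": str})
    _require(df, ("timestamp", "type", "has_stim"), path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "event_id" not in df.columns:
        df["event_id"] = [f"EV{i:06d}" for i in range(len(df))]
    offs = []
    for i, cell in enumerate(df.get("stim_offsets_s", pd.Series([""] * len(df)))):
        if pd.isna(cell) or cell == "":
            offs.append([])
            continue
        try:
            offs.append([float(x) for x in str(cell).split(";")])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i + 2}: bad stim offsets {cell!r}"
            ) from exc
    df["stim_offsets_s"] = offs
    df["has_stim"] = df["has_stim"].astype(bool)
    return EventCatalog(frame=df)


def write_ground_truth_json(path, ground_truth) -> None:
    cfg = ground_truth.config
    payload = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()
        },
        "start": str(ground_truth.start),
        "true_period_days": ground_truth.true_period_days,
        "le_times": [
            str(t)
            for t in (
                ground_truth.le_times
                if ground_truth.le_times is not None
                else []
            )
        ],
        "se_truth": ground_truth.se_truth.to_dict("list")
        if ground_truth.se_truth is not None
        else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def load_table1() -> pd.DataFrame:
    """Packaged per-patient demographics/cycle fixture (20 patients)."""
    with resources.files("multidien.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    assert len(df) == 20
    return df


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
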