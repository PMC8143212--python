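"""CSV/JSON interchange for traces, diameters and fit results.

Trace tables use the long schema ``repeat_id, condition, time_s,
intensity_au``; diameter tables ``event_id, measurement_um``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TimeCourse

__all__ = [
    "traces_to_frame",
    "frame_to_traces",
    "write_traces_csv",
    "read_traces_csv",
    "write_diameters_csv",
    "read_diameters_csv",
    "write_json",
]

TRACE_COLUMNS = ["repeat_id", "condition", "time_s", "intensity_au"]
DIAMETER_COLUMNS = ["event_id", "measurement_um"]


def traces_to_frame(traces: list[TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in traces:
        rows.append(
            pd.DataFrame(
                {
                    "repeat_id": tc.repeat_id,
                    "condition": tc.condition,
                    "time_s": tc.times,
                    "intensity_au": tc.intensities,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[TimeCourse]:
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")
    out = []
    for (rid, cond), grp in df.groupby(["repeat_id", "condition"], sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            TimeCourse(
                grp["time_s"].to_numpy(float),
                grp["intensity_au"].to_numpy(float),
                condition=str(cond),
                repeat_id=str(rid),
            )
        )
    return out


def write_traces_csv(traces: list[TimeCourse], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[TimeCourse]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no trace rows")
    return frame_to_traces(df)


def write_diameters_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_diameters_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DIAMETER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"diameter table is missing columns: {sorted(missing)}")
    return df


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_Encoder, allow_nan=True))
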