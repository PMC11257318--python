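"""Readers for the three raw sources and change-triggered event consolidation.

The smartwatch records a sensor only when its value changes, so each raw row
carries one sensor. Consolidation rebuilds complete per-timestamp records by
carrying every state sensor's last value forward (last value carried forward);
the step detector is an impulse, not a state: a consolidated record stores the
count of step events at that exact timestamp and is never forward-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Fixed sensor catalog and the consolidated column(s) each sensor feeds.
SENSOR_COLUMNS: dict[str, list[str]] = {
    "heart_rate": ["heart_rate"],
    "step_detector": ["steps"],
    "accelerometer": ["accel_x", "accel_y", "accel_z"],
    "gyroscope": ["gyro_x", "gyro_y", "gyro_z"],
    "gravity": ["gravity_x", "gravity_y", "gravity_z"],
    "magnetometer": ["mag_x", "mag_y", "mag_z"],
}
VECTOR_SENSORS = {"accelerometer", "gyroscope", "gravity", "magnetometer"}
#: State channels are forward-filled; the steps channel is a per-timestamp count.
STATE_COLUMNS: list[str] = [
    c for s, cols in SENSOR_COLUMNS.items() if s != "step_detector" for c in cols
]
WATCH_COLUMNS: list[str] = STATE_COLUMNS + ["steps"]


@dataclass(frozen=True)
class ActivityInterval:
    start: float
    end: float
    type: str  # EAT or DRINK

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("activity interval needs start < end")
        if self.type not in ("EAT", "DRINK"):
            raise ValueError(f"unknown activity type {self.type!r}")


def _parse_timestamps(raw: pd.Series, path, column: str) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed {column} timestamp at line {line}")
    return ts.astype("int64") / 1e9  # epoch seconds


def read_cgm(path) -> pd.DataFrame:
    """Read cgm.csv -> DataFrame(timestamp_s, glucose_mg_dl), sorted.

    Rows may arrive out of order and are sorted; duplicate timestamps (device
    re-uploads) are rejected rather than silently deduplicated.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["timestamp", "glucose_mg_dl"]:
        raise ValueError(f"{path}: expected columns timestamp,glucose_mg_dl")
    if df.empty:
        return pd.DataFrame({"timestamp_s": pd.Series(dtype=float),
                             "glucose_mg_dl": pd.Series(dtype=float)})
    ts = _parse_timestamps(df["timestamp"], path, "timestamp")
    glucose = pd.to_numeric(df["glucose_mg_dl"], errors="coerce")
    bad = glucose.isna() | (glucose <= 0)
    if bad.any():
        raise ValueError(
            f"{path}: non-positive or malformed glucose at line {int(bad.idxmax()) + 2}"
        )
    out = pd.DataFrame({"timestamp_s": ts, "glucose_mg_dl": glucose.astype(float)})
    out = out.sort_values("timestamp_s", kind="stable").reset_index(drop=True)
    if out["timestamp_s"].duplicated().any():
        raise ValueError(f"{path}: duplicate CGM timestamps")
    return out


def read_sensor_events(path) -> pd.DataFrame:
    """Read sensors.csv -> DataFrame(timestamp_ms, sensor, v1, v2, v3).

    Output is sorted by (timestamp, file order); unknown sensors, incomplete
    3-vectors and non-positive heart rates are rejected.
    """
    df = pd.read_csv(path)
    expected = ["timestamp_ms", "sensor", "v1", "v2", "v3"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {','.join(expected)}")
    unknown = ~df["sensor"].isin(SENSOR_COLUMNS)
    if unknown.any():
        raise ValueError(
            f"{path}: unknown sensor {df['sensor'][unknown].iloc[0]!r} "
            f"at line {int(unknown.idxmax()) + 2}"
        )
    is_vec = df["sensor"].isin(VECTOR_SENSORS)
    missing = is_vec & (df["v1"].isna() | df["v2"].isna() | df["v3"].isna())
    if missing.any():
        raise ValueError(
            f"{path}: missing vector component at line {int(missing.idxmax()) + 2}"
        )
    bad_hr = (df["sensor"] == "heart_rate") & (df["v1"].isna() | (df["v1"] <= 0))
    if bad_hr.any():
        raise ValueError(
            f"{path}: non-positive heart rate at line {int(bad_hr.idxmax()) + 2}"
        )
    df = df.astype({"timestamp_ms": np.int64})
    return df.sort_values("timestamp_ms", kind="stable").reset_index(drop=True)


def read_activities(path) -> pd.DataFrame:
    """Read activities.csv -> DataFrame(start_s, end_s, type), sorted by start."""
    df = pd.read_csv(path)
    if list(df.columns) != ["start", "end", "type"]:
        raise ValueError(f"{path}: expected columns start,end,type")
    if df.empty:
        return pd.DataFrame({"start_s": pd.Series(dtype=float),
                             "end_s": pd.Series(dtype=float), "type": pd.Series(dtype=object)})
    out = pd.DataFrame(
        {
            "start_s": _parse_timestamps(df["start"], path, "start"),
            "end_s": _parse_timestamps(df["end"], path, "end"),
            "type": df["type"],
        }
    )
    for row in out.itertuples(index=False):
        ActivityInterval(row.start_s, row.end_s, row.type)  # validates
    return out.sort_values("start_s", kind="stable").reset_index(drop=True)


def consolidate_events(events: pd.DataFrame) -> pd.DataFrame:
    """One record per distinct event timestamp with every sensor's latest value.

    State sensors are carried forward from their last event and are NaN before
    their first; ``steps`` holds the number of step events at that exact
    timestamp. Simultaneous events merge into one record, last parse order
    winning per sensor. Input must be sorted by timestamp.
    """
    ts = events["timestamp_ms"].to_numpy()
    if np.any(np.diff(ts) < 0):
        raise ValueError("events must be sorted by timestamp_ms")
    stamps = np.unique(ts)
    out = pd.DataFrame(index=pd.Index(stamps, name="timestamp_ms"))

    # long form: one (timestamp, column, value) triple per sensor axis
    for sensor, cols in SENSOR_COLUMNS.items():
        sub = events[events["sensor"] == sensor]
        if sensor == "step_detector":
            counts = sub.groupby("timestamp_ms").size()
            out["steps"] = counts.reindex(stamps, fill_value=0).astype(np.int64)
            continue
        for axis, col in enumerate(cols):
            vals = sub.groupby("timestamp_ms")[f"v{axis + 1}"].last()
            out[col] = vals.reindex(stamps).ffill()
    if "steps" not in out:
        out["steps"] = np.int64(0)
    return out.reset_index()[["timestamp_ms"] + WATCH_COLUMNS]


def write_consolidated(records: pd.DataFrame, path) -> None:
    """Dump the consolidated stream for inspection."""
    records.to_csv(path, index=False)
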