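"""Fuse the consolidated streams into 1 Hz series and cut observation windows.

The consolidated sensor records are irregular; piecewise aggregate
approximation (PAA) reduces each state channel to one value per second (the
time-weighted mean of its piecewise-constant trace), the step detector to a
per-second count, glucose to a zero-order hold of the latest CGM reading, and
the activity log to a per-second label (0 none, 1 eat, 2 drink). Wear
segmentation splits the timeline at sensor silences; sliding observation
windows with their horizon targets are cut inside single segments only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import STATE_COLUMNS, WATCH_COLUMNS, consolidate_events

#: Canonical channel order of a fully fused series.
ALL_CHANNELS: tuple[str, ...] = ("glucose", "heart_rate", "steps", "activity") + tuple(
    c for c in STATE_COLUMNS if c != "heart_rate"
)
DEFAULT_COMBO: tuple[str, ...] = ("glucose", "heart_rate", "steps")


@dataclass
class RegularSeries:
    """Uniformly sampled (1 Hz) multichannel series.

    ``data`` is indexed by absolute second; ``event_mask`` flags seconds that
    contained at least one raw sensor event (used for wear segmentation).
    """

    start: int
    data: pd.DataFrame
    event_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.data)

    @property
    def seconds(self) -> np.ndarray:
        return self.data.index.to_numpy()


def paa_downsample(records: pd.DataFrame) -> RegularSeries:
    """Collapse consolidated records to 1 Hz (watch channels only).

    State channels carry the time-weighted mean of their last-value-carried-
    forward trace over each second; ``steps`` counts step events per second.
    """
    if records.empty:
        return RegularSeries(0, pd.DataFrame(columns=WATCH_COLUMNS), np.zeros(0, bool))
    ts = records["timestamp_ms"].to_numpy(np.int64)
    s0 = int(ts[0] // 1000)
    s1 = int(ts[-1] // 1000)
    n_sec = s1 - s0 + 1
    bounds = np.arange(s0, s1 + 2, dtype=np.int64) * 1000
    merged = np.unique(np.concatenate([ts, bounds]))
    starts = merged[:-1]
    widths = np.diff(merged) / 1000.0
    rec_idx = np.searchsorted(ts, starts, side="right") - 1
    sec_idx = (starts // 1000 - s0).astype(np.int64)

    out = {}
    observed = rec_idx >= 0
    for col in STATE_COLUMNS:
        v = records[col].to_numpy(np.float64)
        vals = np.where(observed, v[np.maximum(rec_idx, 0)], np.nan)
        valid = ~np.isnan(vals)
        num = np.bincount(sec_idx[valid], weights=vals[valid] * widths[valid], minlength=n_sec)
        cov = np.bincount(sec_idx[valid], weights=widths[valid], minlength=n_sec)
        mean = np.full(n_sec, np.nan)
        ok = cov > 1e-12
        mean[ok] = num[ok] / cov[ok]
        out[col] = mean

    steps_sec = (ts // 1000 - s0).astype(np.int64)
    out["steps"] = np.bincount(
        steps_sec, weights=records["steps"].to_numpy(np.float64), minlength=n_sec
    )

    event_mask = np.zeros(n_sec, dtype=bool)
    event_mask[np.unique(steps_sec)] = True
    data = pd.DataFrame(out, index=pd.RangeIndex(s0, s1 + 1))[WATCH_COLUMNS]
    return RegularSeries(s0, data, event_mask)


def align_glucose(cgm: pd.DataFrame, seconds: np.ndarray) -> np.ndarray:
    """Zero-order hold of CGM readings onto a 1 Hz grid (NaN before first)."""
    t = np.round(cgm["timestamp_s"].to_numpy(np.float64)).astype(np.int64)
    v = cgm["glucose_mg_dl"].to_numpy(np.float64)
    idx = np.searchsorted(t, seconds, side="right") - 1
    out = np.where(idx >= 0, v[np.maximum(idx, 0)], np.nan)
    return out


def encode_activity(activities: pd.DataFrame, seconds: np.ndarray) -> np.ndarray:
    """Label each second 0/1/2 (none/eat/drink).

    A second inside overlapping intervals takes the later-starting interval's
    label; ties break to DRINK (the higher code).
    """
    labels = np.zeros(len(seconds), dtype=np.int8)
    if activities.empty:
        return labels
    code = activities["type"].map({"EAT": 1, "DRINK": 2}).to_numpy(np.int8)
    order = np.lexsort((code, activities["start_s"].to_numpy()))
    starts = activities["start_s"].to_numpy(np.float64)
    ends = activities["end_s"].to_numpy(np.float64)
    for i in order:
        lo = np.searchsorted(seconds, starts[i], side="left")
        hi = np.searchsorted(seconds, ends[i], side="left")  # half-open [start, end)
        labels[lo:hi] = code[i]
    return labels


def build_regular_series(
    records: pd.DataFrame, cgm: pd.DataFrame, activities: pd.DataFrame
) -> RegularSeries:
    """Assemble the full fused series: watch channels + glucose + activity."""
    series = paa_downsample(records)
    secs = series.seconds
    series.data["glucose"] = align_glucose(cgm, secs)
    series.data["activity"] = encode_activity(activities, secs)
    series.data = series.data[list(ALL_CHANNELS)]
    return series


def segment_wear(
    series: RegularSeries,
    max_gap_seconds: int = 10,
    required: Sequence[str] = ("glucose", "heart_rate"),
) -> list[RegularSeries]:
    """Split into maximal continuous wear segments.

    A segment is a run of seconds in which every required channel is present
    and no sensor-silence gap exceeds ``max_gap_seconds`` (overnight non-wear
    produces long silences and therefore segment boundaries).
    """
    if len(series) == 0:
        return []
    mask = series.event_mask.copy()
    # keep short silences: fill False runs of length <= max_gap between events
    ev = np.flatnonzero(series.event_mask)
    if len(ev) == 0:
        return []
    for a, b in zip(ev[:-1], ev[1:]):
        if b - a - 1 <= max_gap_seconds:
            mask[a : b + 1] = True
    for ch in required:
        mask &= series.data[ch].notna().to_numpy()

    segments = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for lo, hi in zip(edges[::2], edges[1::2]):
        segments.append(
            RegularSeries(
                int(series.start + lo),
                series.data.iloc[lo:hi],
                series.event_mask[lo:hi],
            )
        )
    return segments


# ---------------------------------------------------------------------------
# min-max scaling


@dataclass(frozen=True)
class ScalingStats:
    """Per-channel minimum/maximum observed on the fitting split."""

    channels: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mins > self.maxs):
            raise ValueError("per-channel min must not exceed max")


def minmax_fit(segments: Sequence[RegularSeries], channels: Sequence[str] | None = None) -> ScalingStats:
    if not segments:
        raise ValueError("cannot fit scaling on an empty split")
    channels = tuple(channels or segments[0].data.columns)
    stacked = np.vstack([s.data[list(channels)].to_numpy(np.float64) for s in segments])
    return ScalingStats(channels, np.nanmin(stacked, axis=0), np.nanmax(stacked, axis=0))


def _scale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi - lo <= 0:
        return np.zeros_like(values)  # constant channel maps to 0
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def minmax_apply(series: RegularSeries, stats: ScalingStats) -> RegularSeries:
    data = series.data.copy()
    for i, ch in enumerate(stats.channels):
        data[ch] = _scale(data[ch].to_numpy(np.float64), stats.mins[i], stats.maxs[i])
    return replace(series, data=data)


def window_minmax_fit(X: np.ndarray, channels: Sequence[str]) -> ScalingStats:
    """Fit scaling stats on a window block (n, C, T), e.g. a training fold."""
    return ScalingStats(
        tuple(channels),
        X.min(axis=(0, 2)) if len(X) else np.zeros(len(channels)),
        X.max(axis=(0, 2)) if len(X) else np.zeros(len(channels)),
    )


def window_minmax_apply(X: np.ndarray, stats: ScalingStats) -> np.ndarray:
    out = np.empty_like(X, dtype=np.float64)
    for i in range(X.shape[1]):
        out[:, i, :] = _scale(X[:, i, :], stats.mins[i], stats.maxs[i])
    return out


# ---------------------------------------------------------------------------
# observation windows


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: W minutes observed, target H minutes ahead."""

    observation_minutes: int
    horizon_minutes: int
    stride_seconds: int = 300
    channels: tuple[str, ...] = DEFAULT_COMBO

    def __post_init__(self) -> None:
        if self.observation_minutes <= 0 or self.horizon_minutes <= 0:
            raise ValueError("observation and horizon must be positive")
        if self.stride_seconds <= 0:
            raise ValueError("stride must be positive")


@dataclass
class WindowSet:
    """Stacked observation windows: X (n, channels, W*60), targets in mg/dL."""

    X: np.ndarray
    y: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    channels: tuple[str, ...]
    spec: WindowSpec

    def __len__(self) -> int:
        return len(self.y)


def build_windows(
    segments: Sequence[RegularSeries],
    spec: WindowSpec,
    cgm: pd.DataFrame | None = None,
) -> WindowSet:
    """Cut sliding windows; window and target must share one wear segment.

    When ``cgm`` is given a window is emitted only if its target second
    coincides with an actual CGM measurement, and ``y`` is that measurement
    (raw mg/dL, never scaled). Without ``cgm`` the glucose channel value at
    the target second is used (every candidate is a valid target). Windows
    containing missing values are dropped.
    """
    w_sec = spec.observation_minutes * 60
    h_sec = spec.horizon_minutes * 60
    chans = list(spec.channels)
    if cgm is not None:
        cgm_t = np.round(cgm["timestamp_s"].to_numpy(np.float64)).astype(np.int64)
        cgm_v = cgm["glucose_mg_dl"].to_numpy(np.float64)
        cgm_set = set(cgm_t.tolist())

    xs, ys, t0s, t1s = [], [], [], []
    for seg in segments:
        L = len(seg)
        if L < w_sec + h_sec:
            continue
        start, end = int(seg.start), int(seg.start) + L - 1
        base = start + w_sec - 1
        if cgm is not None:
            # phase-align the first window end so targets hit CGM ticks
            off = next(
                (o for o in range(spec.stride_seconds) if base + o + h_sec in cgm_set),
                None,
            )
            if off is None:
                continue
            base += off
        cand = np.arange(base, end - h_sec + 1, spec.stride_seconds)
        targets = cand + h_sec
        if cgm is not None:
            keep = np.isin(targets, cgm_t)
            cand, targets = cand[keep], targets[keep]
        if len(cand) == 0:
            continue
        block = seg.data[chans].to_numpy(np.float64).T  # (C, L)
        if cgm is not None:
            y_seg = cgm_v[np.searchsorted(cgm_t, targets)]
        else:
            y_seg = seg.data["glucose"].to_numpy(np.float64)[targets - start]
        for t_end, y in zip(cand, y_seg):
            pos = t_end - start
            Xw = block[:, pos - w_sec + 1 : pos + 1]
            if np.isnan(Xw).any() or np.isnan(y):
                continue
            xs.append(Xw)
            ys.append(y)
            t0s.append(t_end - w_sec + 1)
            t1s.append(t_end)
    n = len(xs)
    X = np.stack(xs) if n else np.zeros((0, len(chans), w_sec))
    return WindowSet(
        X,
        np.asarray(ys, dtype=np.float64),
        np.asarray(t0s, dtype=np.int64),
        np.asarray(t1s, dtype=np.int64),
        tuple(chans),
        spec,
    )


def save_windows(ws: WindowSet, path) -> None:
    """Persist a window set: binary block plus a JSON provenance sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), X=ws.X, y=ws.y, t_start=ws.t_start, t_end=ws.t_end)
    digest = hashlib.sha256(ws.X.tobytes() + ws.y.tobytes()).hexdigest()
    sidecar = {
        "channels": list(ws.channels),
        "observation_minutes": ws.spec.observation_minutes,
        "horizon_minutes": ws.spec.horizon_minutes,
        "stride_seconds": ws.spec.stride_seconds,
        "n_windows": len(ws),
        "sha256": digest,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    pd.DataFrame({"t_end": ws.t_end, "y_mg_dl": ws.y}).to_csv(
        path.with_suffix(".targets.csv"), index=False
    )


def load_windows(path) -> WindowSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrs = np.load(path.with_suffix(".npz"))
    spec = WindowSpec(
        meta["observation_minutes"],
        meta["horizon_minutes"],
        meta["stride_seconds"],
        tuple(meta["channels"]),
    )
    ws = WindowSet(
        arrs["X"], arrs["y"], arrs["t_start"], arrs["t_end"], tuple(meta["channels"]), spec
    )
    digest = hashlib.sha256(ws.X.tobytes() + ws.y.tobytes()).hexdigest()
    if digest != meta["sha256"]:
        raise ValueError(f"{path}: window container hash mismatch")
    return ws


# ---------------------------------------------------------------------------
# participant-level glue


@dataclass
class ParticipantData:
    """Fused wear segments plus the raw CGM record for target lookup."""

    segments: list[RegularSeries]
    cgm: pd.DataFrame


def prepare_participant(
    records: pd.DataFrame,
    cgm: pd.DataFrame,
    activities: pd.DataFrame,
    max_gap_seconds: int = 10,
    required: Sequence[str] = ("glucose", "heart_rate"),
) -> ParticipantData:
    series = build_regular_series(records, cgm, activities)
    return ParticipantData(segment_wear(series, max_gap_seconds, required), cgm)


def prepare_bundle(bundle, max_gap_seconds: int = 10) -> ParticipantData:
    """Run ingestion + fusion on an in-memory synthetic RawBundle."""
    records = consolidate_events(bundle.events)
    return prepare_participant(records, bundle.cgm, bundle.activities, max_gap_seconds)


def prepare_dir(path, max_gap_seconds: int = 10) -> ParticipantData:
    """Run ingestion + fusion on a participant directory of the CSV dialects."""
    from .ingest import read_activities, read_cgm, read_sensor_events

    path = Path(path)
    records = consolidate_events(read_sensor_events(path / "sensors.csv"))
    return prepare_participant(
        records, read_cgm(path / "cgm.csv"), read_activities(path / "activities.csv"),
        max_gap_seconds,
    )
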