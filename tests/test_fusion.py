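"""PAA downsampling, channel alignment, segmentation, scaling, windowing."""

import numpy as np
import pandas as pd
import pytest

from glucowear.fusion import (
    ALL_CHANNELS,
    RegularSeries,
    ScalingStats,
    WindowSpec,
    align_glucose,
    build_windows,
    encode_activity,
    load_windows,
    minmax_apply,
    minmax_fit,
    paa_downsample,
    save_windows,
    segment_wear,
    window_minmax_apply,
    window_minmax_fit,
)
from glucowear.ingest import WATCH_COLUMNS


def records_from(rows):
    """rows: list of (timestamp_ms, {column: value}) -> consolidated frame."""
    df = pd.DataFrame(
        [{"timestamp_ms": t, **{c: np.nan for c in WATCH_COLUMNS}, **vals}
         for t, vals in rows]
    )
    state = [c for c in WATCH_COLUMNS if c != "steps"]
    df[state] = df[state].ffill()
    df["steps"] = df["steps"].fillna(0)
    return df[["timestamp_ms"] + WATCH_COLUMNS]


class TestPaa:
    def test_constant_value_passes_through(self):
        rec = records_from([(0, {"heart_rate": 80.0}), (3000, {"heart_rate": 80.0})])
        series = paa_downsample(rec)
        assert np.allclose(series.data["heart_rate"], 80.0)

    def test_time_weighted_mean_within_second(self):
        # 60 bpm for the first half-second, then 62 -> mean 61
        rec = records_from(
            [(0, {"heart_rate": 60.0}), (500, {"heart_rate": 62.0}),
             (2000, {"heart_rate": 62.0})]
        )
        series = paa_downsample(rec)
        assert series.data["heart_rate"].iloc[0] == pytest.approx(61.0)

    def test_step_events_counted_per_second(self):
        rec = records_from(
            [(100, {"steps": 1}), (400, {"steps": 1}), (900, {"steps": 1}),
             (1500, {"steps": 1})]
        )
        series = paa_downsample(rec)
        assert series.data["steps"].tolist() == [3, 1]

    def test_missing_before_first_event_of_channel(self):
        rec = records_from(
            [(0, {"heart_rate": 70.0}), (2500, {"accel_x": 1.0, "accel_y": 0.0,
                                                "accel_z": 9.8})]
        )
        series = paa_downsample(rec)
        assert series.data["accel_x"].isna().iloc[0]
        assert series.data["heart_rate"].notna().all()

    def test_empty_records_give_empty_series(self):
        rec = pd.DataFrame(columns=["timestamp_ms"] + WATCH_COLUMNS)
        assert len(paa_downsample(rec)) == 0

    def test_minute_aggregation_consistency(self, rng):
        # PAA to seconds then a minute mean equals the direct time-weighted
        # minute mean of the piecewise-constant trace
        times = np.sort(rng.choice(np.arange(0, 60_000, 10), 40, replace=False))
        times[0] = 0
        times[-1] = 59_990  # trace must span the whole minute
        vals = rng.uniform(50, 120, size=len(times))
        rec = records_from([(int(t), {"heart_rate": v}) for t, v in zip(times, vals)])
        series = paa_downsample(rec)
        per_second = series.data["heart_rate"].to_numpy()[:60]
        # direct integral oracle over [0, 60 s)
        bounds = np.append(times / 1000.0, 60.0)
        direct = np.sum(vals * np.diff(bounds)) / 60.0
        assert per_second.mean() == pytest.approx(direct, abs=1e-9)


class TestAlignment:
    cgm = pd.DataFrame({"timestamp_s": [300.0, 600.0], "glucose_mg_dl": [110.0, 130.0]})

    def test_second_on_cgm_tick_takes_that_reading(self):
        out = align_glucose(self.cgm, np.array([300]))
        assert out[0] == 110.0

    def test_zero_order_hold_between_readings(self):
        out = align_glucose(self.cgm, np.array([500]))
        assert out[0] == 110.0  # 200 s after the 110 reading, next at +300 s

    def test_missing_before_first_reading(self):
        out = align_glucose(self.cgm, np.array([299]))
        assert np.isnan(out[0])


class TestActivityEncoding:
    def test_labels(self):
        acts = pd.DataFrame(
            {"start_s": [10.0, 40.0], "end_s": [20.0, 50.0], "type": ["EAT", "DRINK"]}
        )
        secs = np.arange(0, 60)
        labels = encode_activity(acts, secs)
        assert labels[15] == 1 and labels[45] == 2 and labels[5] == 0
        assert labels[20] == 0  # half-open interval

    def test_overlap_later_start_wins_tie_breaks_to_drink(self):
        secs = np.arange(0, 100)
        overlap = pd.DataFrame(
            {"start_s": [10.0, 30.0], "end_s": [80.0, 60.0], "type": ["EAT", "DRINK"]}
        )
        labels = encode_activity(overlap, secs)
        # exhaustive small-case oracle of the tie rule
        assert labels[35] == 2 and labels[15] == 1 and labels[70] == 1
        tie = pd.DataFrame(
            {"start_s": [10.0, 10.0], "end_s": [20.0, 20.0], "type": ["EAT", "DRINK"]}
        )
        assert encode_activity(tie, secs)[12] == 2


def make_series(length, start=0, glucose=100.0, gap_at=None, gap_len=0):
    secs = np.arange(start, start + length)
    data = pd.DataFrame(
        {ch: np.full(length, np.nan) for ch in ALL_CHANNELS}, index=secs
    )
    data["glucose"] = glucose
    data["heart_rate"] = 70.0
    data["steps"] = 0.0
    data["activity"] = 0.0
    mask = np.ones(length, dtype=bool)
    if gap_at is not None:
        mask[gap_at : gap_at + gap_len] = False
    return RegularSeries(start, data, mask)


class TestSegmentation:
    def test_continuous_day_is_one_segment(self):
        segs = segment_wear(make_series(5000), required=("glucose", "heart_rate"))
        assert len(segs) == 1 and len(segs[0]) == 5000

    def test_long_silence_splits_segments(self):
        series = make_series(5000, gap_at=2000, gap_len=100)
        segs = segment_wear(series, max_gap_seconds=10)
        assert len(segs) == 2
        assert segs[0].start == 0 and len(segs[0]) == 2000
        assert segs[1].start == 2100

    def test_short_silence_is_bridged(self):
        series = make_series(5000, gap_at=2000, gap_len=5)
        segs = segment_wear(series, max_gap_seconds=10)
        assert len(segs) == 1

    def test_simulated_wear_periods_recovered(self, one_day_bundle, prepared):
        (w0, w1), = one_day_bundle.schedules[0].wear
        assert len(prepared.segments) == 1
        seg = prepared.segments[0]
        assert abs(seg.start - w0) <= 10
        assert abs((seg.start + len(seg)) - w1) <= 10

    def test_steps_channel_conserves_step_events(self, one_day_bundle, prepared):
        n_steps = (one_day_bundle.events["sensor"] == "step_detector").sum()
        total = sum(s.data["steps"].sum() for s in prepared.segments)
        assert total == n_steps


class TestMinMax:
    def test_endpoint_mapping_and_midpoint(self):
        series = make_series(4)
        series.data["glucose"] = [40.0, 400.0, 220.0, 100.0]
        stats = minmax_fit([series], ["glucose"])
        scaled = minmax_apply(series, stats)
        g = scaled.data["glucose"].to_numpy()
        assert g[0] == 0.0 and g[1] == 1.0 and g[2] == pytest.approx(0.5)

    def test_out_of_range_values_clip(self):
        fit_on = make_series(2)
        fit_on.data["glucose"] = [100.0, 200.0]
        stats = minmax_fit([fit_on], ["glucose"])
        other = make_series(2)
        other.data["glucose"] = [50.0, 500.0]
        g = minmax_apply(other, stats).data["glucose"].to_numpy()
        assert g[0] == 0.0 and g[1] == 1.0

    def test_constant_channel_maps_to_zero(self):
        series = make_series(5)
        stats = minmax_fit([series], ["glucose"])
        assert np.all(minmax_apply(series, stats).data["glucose"] == 0.0)

    def test_invalid_stats_rejected(self):
        with pytest.raises(ValueError):
            ScalingStats(("glucose",), np.array([10.0]), np.array([5.0]))

    def test_window_block_scaling_matches_series_scaling(self, rng):
        X = rng.uniform(60, 200, size=(4, 2, 30))
        stats = window_minmax_fit(X, ("glucose", "heart_rate"))
        Xs = window_minmax_apply(X, stats)
        assert Xs.min() >= 0 and Xs.max() <= 1
        i, j = np.unravel_index(np.argmax(X[:, 0, :]), X[:, 0, :].shape)
        assert Xs[i, 0, j] == 1.0


class TestWindows:
    def test_counts_match_closed_form_examples(self):
        seg = make_series(7200)
        spec = WindowSpec(60, 5, 300, ("glucose", "heart_rate"))
        assert len(build_windows([seg], spec)) == 12  # floor((7200-3900)/300)+1
        spec = WindowSpec(60, 60, 300, ("glucose", "heart_rate"))
        assert len(build_windows([seg], spec)) == 1
        short = make_series(60 * (60 + 5) - 1)
        assert len(build_windows([short], WindowSpec(60, 5, 300, ("glucose",)))) == 0

    def test_counts_match_closed_form_randomized(self, rng):
        for _ in range(25):
            W = int(rng.choice([30, 60, 90]))
            H = int(rng.choice([5, 10, 15, 30, 45, 60]))
            stride = int(rng.choice([60, 300, 900]))
            L = int(rng.integers(1000, 20000))
            seg = make_series(L)
            n = len(build_windows([seg], WindowSpec(W, H, stride, ("glucose",))))
            expected = max(0, (L - 60 * (W + H)) // stride + 1)
            assert n == expected, (L, W, H, stride)

    def test_window_geometry_and_target(self):
        seg = make_series(9000)
        seg.data["glucose"] = np.arange(9000, dtype=float)
        spec = WindowSpec(30, 5, 300, ("glucose",))
        ws = build_windows([seg], spec)
        assert np.all(ws.t_end - ws.t_start + 1 == 1800)
        # X ends exactly at t_end; y is the glucose H*60 s later
        assert ws.X[0, 0, -1] == ws.t_end[0]
        assert ws.y[0] == ws.t_end[0] + 300

    def test_targets_must_hit_cgm_ticks(self):
        seg = make_series(7300, start=17)  # misaligned segment start
        cgm = pd.DataFrame(
            {"timestamp_s": np.arange(0, 7800, 300, dtype=float),
             "glucose_mg_dl": np.full(26, 123.0)}
        )
        ws = build_windows([seg], WindowSpec(60, 5, 300, ("glucose",)), cgm)
        assert len(ws) > 0
        assert np.all((ws.t_end + 300) % 300 == 0)
        assert np.all(ws.y == 123.0)

    def test_windows_never_cross_segments(self):
        segs = [make_series(4000), make_series(4000, start=10000)]
        ws = build_windows(segs, WindowSpec(30, 5, 300, ("glucose",)))
        inside = ((ws.t_start >= 0) & (ws.t_end + 300 < 4000)) | (
            (ws.t_start >= 10000) & (ws.t_end + 300 < 14000)
        )
        assert inside.all()

    def test_save_load_roundtrip(self, tmp_path, rng):
        seg = make_series(5000)
        seg.data["glucose"] = rng.uniform(80, 200, 5000)
        ws = build_windows([seg], WindowSpec(30, 5, 300, ("glucose", "heart_rate")))
        save_windows(ws, tmp_path / "w")
        back = load_windows(tmp_path / "w")
        assert np.array_equal(back.X, ws.X) and np.array_equal(back.y, ws.y)
        assert back.channels == ws.channels
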