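"""Synthetic wearable-data generator.

Emulates one study participant wearing a 5-minute-cadence CGM together with a
smartwatch whose sensors (heart rate, step detector, four motion sensors) are
recorded change-triggered and only during a daytime wear window, plus a
manually kept eat/drink activity log with realistic under-recording.

The latent physiology is a deliberately minimal mechanistic model — gamma-shaped
carbohydrate appearance, first-order glucose clearance, and exercise-amplified
glucose uptake driven by exponentially smoothed step rate E(t):

    dG/dt = -k_clear (G - G_b) + k_meal M(t)
            - [k_now E(t) + k_late E(t - delay)] (G - G_floor) + noise

Exercise acts through two pathways: a modest uptake during the bout and a
larger delayed one (glycogen repletion, the mechanism behind delayed
post-exercise hypoglycemia). The delayed pathway is what makes heart rate and
step history genuinely predictive of future glucose beyond what the CGM trace
itself reveals. The model is a statistical stand-in that endows the synthetic
streams with the couplings the forecasting pipeline exploits, not a validated
medical model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._fast import euler_glucose, recursive_filter

SECONDS_PER_DAY = 86_400
CGM_PERIOD_S = 300
#: Epoch used when serialising relative simulation seconds to ISO-8601.
BASE_TIME = pd.Timestamp("2024-01-01T00:00:00+00:00")

EAT, DRINK = "EAT", "DRINK"

MOTION_SENSORS = ("accelerometer", "gyroscope", "gravity", "magnetometer")
# per-axis (mean, sd) of the uninformative motion noise streams
_MOTION_STATS = {
    "accelerometer": ((0.0, 0.0, 9.8), 0.3),
    "gyroscope": ((0.0, 0.0, 0.0), 0.1),
    "gravity": ((0.0, 0.0, 9.81), 0.05),
    "magnetometer": ((22.0, 5.0, 41.0), 0.5),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    Rates are per minute, times of day in hours, glucose in mg/dL, heart rate
    in bpm, carbohydrates in grams.
    """

    n_days: int = 5
    wear_start: float = 8.0
    wear_end: float = 20.0
    baseline_glucose: float = 95.0
    clearance_rate: float = 0.01          # 1/min
    meal_tau: float = 40.0                # min, carb-absorption time constant
    meal_gain: float | None = None        # (mg/dL)/g; None -> calibrated
    exercise_gain: float = 0.03           # 1/min per (step/s), delayed pathway
    exercise_gain_immediate: float = 0.01  # 1/min per (step/s), during-bout uptake
    exercise_delay: float = 40.0          # min dead time of the delayed pathway
    hr_rest: float = 65.0
    hr_gain: float = 55.0                 # bpm per (step/s)
    process_noise_sd: float = 0.4         # mg/dL min^-1/2
    cgm_noise_sd: float = 2.0             # mg/dL
    activity_dropout_p: float = 0.3
    meals_per_day: int = 3
    exercise_bouts_per_day: int = 1
    carb_range: tuple[float, float] = (30.0, 90.0)
    cadence: float = 1.7                  # steps/s at full intensity
    glucose_floor: float = 40.0           # mg/dL, lower bound of the drift
    drink_fraction: float = 0.25          # probability a meal event is a drink
    drink_carb_p: float = 0.5             # probability a drink carries carbs
    exercise_smoothing_tau: float = 15.0  # min, step-rate smoothing
    hr_noise_sd: float = 2.0              # bpm
    hr_noise_tau: float = 60.0            # s, OU time constant of HR noise
    motion_event_period: float = 6.0      # s between each motion sensor's events
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.meals_per_day < 0 or self.exercise_bouts_per_day < 0:
            raise ValueError("counts must be non-negative (n_days >= 1)")
        for name in (
            "clearance_rate", "meal_tau", "exercise_gain", "exercise_gain_immediate",
            "exercise_delay", "process_noise_sd", "cgm_noise_sd", "hr_noise_sd",
            "cadence", "exercise_smoothing_tau",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.activity_dropout_p <= 1.0:
            raise ValueError("activity_dropout_p must lie in [0, 1]")
        if not 0.0 <= self.wear_start < self.wear_end <= 24.0:
            raise ValueError("need 0 <= wear_start < wear_end <= 24")
        if self.carb_range[0] > self.carb_range[1] or self.carb_range[0] < 0:
            raise ValueError("carb_range must be a non-negative (lo, hi) pair")
        if self.baseline_glucose <= self.glucose_floor:
            raise ValueError("baseline_glucose must exceed glucose_floor")

    def resolved_meal_gain(self) -> float:
        """meal_gain, calibrated unless given: a 60 g meal peaks ~70 mg/dL."""
        if self.meal_gain is not None:
            return self.meal_gain
        return 70.0 / (60.0 * _unit_meal_peak(self.meal_tau, self.clearance_rate))

    def for_participant(self, participant: int) -> "SimConfig":
        """Derive an independent per-participant configuration (new seed)."""
        sub = int(np.random.SeedSequence([self.seed, participant]).generate_state(1)[0])
        return dataclasses.replace(self, seed=sub % 2**31)


def _unit_meal_peak(tau: float, k_clear: float) -> float:
    """Peak of the glucose impulse response to 1 g of carbohydrate.

    Closed form for the gamma(shape 2) appearance rate t/tau^2 e^{-t/tau}
    convolved with first-order clearance e^{-k t}.
    """
    a, k = 1.0 / tau, k_clear
    t = np.arange(0.0, 12.0 * tau, 0.05)  # minutes
    if abs(a - k) < 1e-9:
        h = a * a * t * t / 2.0 * np.exp(-a * t)
    else:
        h = (a * a / (a - k) ** 2) * (
            np.exp(-k * t) - np.exp(-a * t) * (1.0 + (a - k) * t)
        )
    return float(h.max())


@dataclass(frozen=True)
class MealEvent:
    start: int            # s from day start
    duration: int         # s
    carbs: float          # g as logged/scheduled
    kind: str             # EAT or DRINK
    carbs_absorbed: float  # g actually absorbed (drinks may carry none)


@dataclass(frozen=True)
class ExerciseBout:
    start: int
    duration: int
    intensity: float      # (0, 1], fraction of full walking cadence


@dataclass(frozen=True)
class DaySchedule:
    day_index: int
    meals: tuple[MealEvent, ...]
    exercise: tuple[ExerciseBout, ...]
    wear: tuple[tuple[int, int], ...]  # (start_s, end_s) half-open


@dataclass
class LatentTraces:
    """Ground-truth per-second traces over the whole simulation."""

    glucose: np.ndarray      # mg/dL
    heart_rate: np.ndarray   # bpm
    step_rate: np.ndarray    # steps/s
    activity: np.ndarray     # {0 none, 1 eat, 2 drink}


@dataclass
class RawBundle:
    """One participant's three raw sources plus the latent truth."""

    cgm: pd.DataFrame         # timestamp_s, glucose_mg_dl
    events: pd.DataFrame      # timestamp_ms, sensor, v1, v2, v3
    activities: pd.DataFrame  # start_s, end_s, type
    latent: LatentTraces
    schedules: tuple[DaySchedule, ...]
    config: SimConfig


def _day_rng(config: SimConfig, day_index: int, stream: int) -> np.random.Generator:
    # counter-based splitting: adding days never perturbs earlier days
    return np.random.default_rng([config.seed, day_index, stream])


def generate_schedule(config: SimConfig, day_index: int) -> DaySchedule:
    """Draw one day's meal events, exercise bouts and wear period."""
    if day_index >= config.n_days:
        raise ValueError("day_index out of range for config.n_days")
    rng = _day_rng(config, day_index, 0)
    w0 = int(config.wear_start * 3600)
    w1 = int(config.wear_end * 3600)

    meals = []
    for _ in range(config.meals_per_day):
        start = int(rng.uniform(w0 + 600, w1 - 3600))
        duration = int(rng.uniform(600, 1800))
        carbs = float(rng.uniform(*config.carb_range))
        kind = DRINK if rng.random() < config.drink_fraction else EAT
        if kind == DRINK:
            absorbed = carbs if rng.random() < config.drink_carb_p else 0.0
        else:
            absorbed = carbs
        meals.append(MealEvent(start, duration, carbs, kind, absorbed))
    meals.sort(key=lambda m: m.start)

    bouts = []
    for _ in range(config.exercise_bouts_per_day):
        duration = int(rng.uniform(1200, 2400))
        start = int(rng.uniform(w0 + 1800, w1 - duration - 600))
        intensity = float(rng.uniform(0.4, 1.0))
        bouts.append(ExerciseBout(start, duration, intensity))
    bouts.sort(key=lambda b: b.start)

    return DaySchedule(day_index, tuple(meals), tuple(bouts), ((w0, w1),))


def simulate_physiology(
    schedule: DaySchedule, config: SimConfig, initial_glucose: float | None = None
) -> LatentTraces:
    """Integrate one day of latent glucose / heart-rate / step dynamics."""
    n = SECONDS_PER_DAY
    t_s = np.arange(n)

    step_rate = np.zeros(n)
    for b in schedule.exercise:
        step_rate[b.start : b.start + b.duration] = b.intensity * config.cadence

    # exponentially smoothed activity drive E(t), per second
    tau_s = config.exercise_smoothing_tau * 60.0
    decay = np.exp(-1.0 / tau_s)
    smoothed = recursive_filter(step_rate, decay, 1.0 - decay)

    # exercise acts on glucose through two uptake pathways: a modest one
    # during the bout and a larger delayed one (glycogen repletion) with a
    # dead time, mirroring delayed post-exercise hypoglycemia
    shift = int(config.exercise_delay * 60)
    delayed = np.concatenate([np.zeros(shift), smoothed[: n - shift]])
    uptake_drive = (
        config.exercise_gain_immediate * smoothed + config.exercise_gain * delayed
    )

    # carbohydrate appearance rate, g/min
    meal_rate = np.zeros(n)
    tau = config.meal_tau
    for m in schedule.meals:
        tm = (t_s[m.start :] - m.start) / 60.0  # minutes since meal start
        meal_rate[m.start :] += m.carbs_absorbed * tm / tau**2 * np.exp(-tm / tau)

    rng = _day_rng(config, schedule.day_index, 1)
    noise = rng.normal(0.0, config.process_noise_sd, size=n)
    g0 = config.baseline_glucose if initial_glucose is None else initial_glucose
    glucose = euler_glucose(
        g0,
        config.baseline_glucose,
        config.clearance_rate,
        config.resolved_meal_gain(),
        1.0,  # gains are already folded into the uptake drive
        config.glucose_floor,
        meal_rate,
        uptake_drive,
        noise,
    )
    if not np.all(np.isfinite(glucose)):
        raise FloatingPointError("glucose integration produced non-finite values")

    # heart rate: rest + activity drive + clipped OU noise
    a = np.exp(-1.0 / config.hr_noise_tau)
    sd_step = config.hr_noise_sd * np.sqrt(1.0 - a * a)
    z = rng.normal(0.0, sd_step, size=n)
    eta = recursive_filter(z, a, 1.0)
    eta = np.clip(eta, -3.0 * config.hr_noise_sd, 3.0 * config.hr_noise_sd)
    heart_rate = config.hr_rest + config.hr_gain * smoothed + eta

    activity = np.zeros(n, dtype=np.int8)
    for m in sorted(schedule.meals, key=lambda m: (m.start, 1 if m.kind == EAT else 2)):
        activity[m.start : m.start + m.duration] = 1 if m.kind == EAT else 2

    return LatentTraces(glucose, heart_rate, step_rate, activity)


def emit_sources(
    latent: LatentTraces, schedules: Sequence[DaySchedule], config: SimConfig
) -> RawBundle:
    """Sample the three raw sources from latent truth.

    CGM fires every 300 s around the clock; smartwatch sensors emit
    change-triggered events only inside wear periods; the activity log drops
    each scheduled interval with probability ``activity_dropout_p``.
    """
    n = latent.glucose.shape[0]
    n_days = n // SECONDS_PER_DAY

    # --- CGM: fixed 5-minute cadence, additive noise, day and night ---
    cgm_t = np.arange(0, n, CGM_PERIOD_S)
    cgm_noise = np.concatenate(
        [
            _day_rng(config, d, 2).normal(0.0, config.cgm_noise_sd, SECONDS_PER_DAY // CGM_PERIOD_S)
            for d in range(n_days)
        ]
    )
    cgm = pd.DataFrame(
        {"timestamp_s": cgm_t, "glucose_mg_dl": latent.glucose[cgm_t] + cgm_noise}
    )

    # --- smartwatch events, wear periods only ---
    ts_list: list[np.ndarray] = []
    sensor_list: list[np.ndarray] = []
    vals_list: list[np.ndarray] = []

    def add(ts_ms, sensor, v):
        ts_list.append(np.asarray(ts_ms, dtype=np.int64))
        sensor_list.append(np.full(len(ts_ms), sensor, dtype=object))
        v = np.asarray(v, dtype=np.float64)
        if v.ndim == 1:
            v = np.column_stack([v, np.full(len(v), np.nan), np.full(len(v), np.nan)])
        vals_list.append(v)

    rounded_hr = np.round(latent.heart_rate).astype(np.int64)
    cum_steps = np.floor(np.concatenate([[0.0], np.cumsum(latent.step_rate)])).astype(np.int64)

    last_hr: int | None = None
    for day in range(n_days):
        sched = schedules[day]
        mrng = _day_rng(config, day, 3)
        for w0, w1 in sched.wear:
            lo, hi = day * SECONDS_PER_DAY + w0, day * SECONDS_PER_DAY + w1
            # heart rate: emit when the integer-rounded bpm changes
            hr = rounded_hr[lo:hi]
            if last_hr is None:
                change = np.concatenate([[True], hr[1:] != hr[:-1]])
            else:
                change = np.concatenate([[hr[0] != last_hr], hr[1:] != hr[:-1]])
            idx = np.flatnonzero(change)
            if len(hr):
                last_hr = int(hr[-1])
            add((lo + idx) * 1000, "heart_rate", hr[idx].astype(float))
            # step detector: one event per step, spread inside its second
            ks = cum_steps[lo + 1 : hi + 1] - cum_steps[lo:hi]
            sec_idx = np.repeat(np.arange(lo, hi), ks)
            within = np.concatenate(
                [np.arange(1, k + 1) * (1000 // (k + 1)) for k in ks[ks > 0]]
            ) if np.any(ks > 0) else np.array([], dtype=np.int64)
            add(sec_idx * 1000 + within, "step_detector", np.ones(len(sec_idx)))
            # motion sensors: uninformative noise streams at a few-second cadence
            for si, sensor in enumerate(MOTION_SENSORS):
                period = config.motion_event_period
                t = np.arange(lo + si * period / len(MOTION_SENSORS), hi, period)
                mean, sd = _MOTION_STATS[sensor]
                v = np.asarray(mean) + mrng.normal(0.0, sd, size=(len(t), 3))
                add((t * 1000).astype(np.int64), sensor, v)

    events = pd.DataFrame(
        {
            "timestamp_ms": np.concatenate(ts_list) if ts_list else np.array([], dtype=np.int64),
            "sensor": np.concatenate(sensor_list) if sensor_list else np.array([], dtype=object),
        }
    )
    vals = np.vstack(vals_list) if vals_list else np.empty((0, 3))
    events[["v1", "v2", "v3"]] = vals
    events = events.sort_values("timestamp_ms", kind="stable").reset_index(drop=True)

    # --- activity log with dropout ---
    rows = []
    for day in range(n_days):
        arng = _day_rng(config, day, 4)
        base = day * SECONDS_PER_DAY
        for m in schedules[day].meals:
            if arng.random() >= config.activity_dropout_p:
                rows.append((base + m.start, base + m.start + m.duration, m.kind))
    activities = pd.DataFrame(rows, columns=["start_s", "end_s", "type"])

    return RawBundle(cgm, events, activities, latent, tuple(schedules), config)


def simulate_participant(config: SimConfig) -> RawBundle:
    """Generate one participant: schedules, latent physiology, raw sources."""
    schedules = [generate_schedule(config, d) for d in range(config.n_days)]
    days = []
    g0: float | None = None
    for sched in schedules:
        traces = simulate_physiology(sched, config, initial_glucose=g0)
        g0 = float(traces.glucose[-1])
        days.append(traces)
    latent = LatentTraces(
        np.concatenate([d.glucose for d in days]),
        np.concatenate([d.heart_rate for d in days]),
        np.concatenate([d.step_rate for d in days]),
        np.concatenate([d.activity for d in days]),
    )
    return emit_sources(latent, schedules, config)


# ---------------------------------------------------------------------------
# on-disk dialects


def _iso(seconds: np.ndarray) -> pd.Series:
    return pd.Series(BASE_TIME + pd.to_timedelta(seconds, unit="s")).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )


def write_bundle(bundle: RawBundle, out_dir) -> None:
    """Write cgm.csv / sensors.csv / activities.csv (+ latent.csv for tests)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "timestamp": _iso(bundle.cgm["timestamp_s"].to_numpy()),
            "glucose_mg_dl": bundle.cgm["glucose_mg_dl"].round(2),
        }
    ).to_csv(out / "cgm.csv", index=False)
    ev = bundle.events.copy()
    ev["timestamp_ms"] = ev["timestamp_ms"] + int(BASE_TIME.timestamp()) * 1000
    ev.round({"v1": 4, "v2": 4, "v3": 4}).to_csv(out / "sensors.csv", index=False)
    pd.DataFrame(
        {
            "start": _iso(bundle.activities["start_s"].to_numpy()),
            "end": _iso(bundle.activities["end_s"].to_numpy()),
            "type": bundle.activities["type"],
        }
    ).to_csv(out / "activities.csv", index=False)
    lat = pd.DataFrame(
        {
            "t_s": np.arange(len(bundle.latent.glucose)),
            "glucose": bundle.latent.glucose.round(3),
            "heart_rate": bundle.latent.heart_rate.round(3),
            "step_rate": bundle.latent.step_rate.round(3),
            "activity": bundle.latent.activity,
        }
    )
    lat.to_csv(out / "latent.csv", index=False)
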