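"""Synthetic camp cohort generator.

Emulates the data-collection setting of a one-week pediatric type-1-diabetes
sports camp: a latent 1-min glucose trajectory per child driven by meals,
insulin dosing and structured physical activity, observed through a CGM
(5-min) or isCGM (15-min + manual scans) sensor plus a logbook of
self-monitored blood glucose (SMBG), insulin doses, carbohydrate intake and
activity sessions.

The latent model is a sum of impulse responses on top of a circadian
baseline:

    g(t) = baseline(t) + sum_m grams_m * Kc(t - t_m) * carb_gain
                       - S(t) * sum_b dose_b * Ki(t - t_b) * isf
                       - activity drain + AR(1) noise

where ``Kc``/``Ki`` are log-normal-shaped kernels (peak-normalised) with
documented times-to-peak, and ``S(t)`` is a multiplicative insulin-
sensitivity factor combining a static gain — a stated monotone function of
age, BMI and basal-insulin share, so the static characteristics genuinely
shape the dynamics — with an activity-triggered elevation decaying over
roughly 24 h. Kernel shapes and constants are generator parameters, not
claims about physiology.

Meal boluses are dosed with population-average rules (500-rule carb ratio),
while the realised insulin effect uses the participant's own sensitivity:
children with high sensitivity dip after meals, children with low
sensitivity stay elevated. This mismatch is what makes the static features
informative for forecasting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    SENSOR_MAX_MMOL,
    ActivitySession,
    CampSchedule,
    DeviceKind,
    MealSlot,
    ParticipantStatics,
    RawStreams,
)

#: Reference start date of the simulated camp (a Monday; arbitrary).
CAMP_START = pd.Timestamp("2022-06-06 00:00")

#: Truncated-normal population parameters: (mean, sd, low, high).
STATIC_DISTRIBUTIONS = {
    "age": (11.2, 2.1, 7.5, 13.9),
    "bmi": (19.5, 4.2, 13.2, 27.7),
    "weight": (45.1, 16.5, 21.0, 77.8),
    "height": (149.4, 14.1, 125.3, 171.0),
    "diabetes_duration": (3.8, 2.8, 0.5, 9.5),
    "hba1c": (7.2, 0.8, 5.1, 8.5),
    "basal_insulin_pct": (46.1, 12.5, 26.2, 69.4),
    "calculated_total_daily_dose": (0.90, 0.39, 0.31, 1.65),
}

#: Cohort female fraction (5 of 14 children).
FEMALE_FRACTION = 5.0 / 14.0

#: isCGM share of devices (9 of 14 children).
ISCGM_FRACTION = 9.0 / 14.0


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable constants of the latent model and the observation process."""

    # impulse-response times-to-peak, minutes
    tpeak_carb_fast: float = 30.0
    tpeak_carb_mixed: float = 60.0
    tpeak_carb_slow: float = 120.0
    tpeak_insulin_short: float = 75.0
    kernel_sigma: float = 0.5  # log-normal shape parameter
    # effect scales
    carb_gain_numerator: float = 6.0  # mmol/l per gram at peak = this / weight
    isf_numerator: float = 60.0  # mmol/l per IE at peak = this / daily dose
    long_insulin_rate: float = 0.06  # sustained mmol/l drop per IE/day
    activity_gain: float = 0.055  # mmol/l per active-minute at kernel peak
    tpeak_activity: float = 20.0
    sensitivity_elevation: float = 0.5  # relative S rise after 60 min exercise
    sensitivity_decay_min: float = 24.0 * 60.0
    # circadian baseline
    base_level: float = 9.6  # ADAG mean glucose at HbA1c 7.2 plus basal offset
    hba1c_level_slope: float = 1.59  # ADAG slope, mmol/l per % HbA1c
    dawn_amplitude: float = 0.6
    dawn_age_slope: float = 0.08  # stronger dawn rise in older children
    dawn_hour: float = 6.0
    dawn_width_h: float = 2.5
    # noise: lag-1 persistence at 5-min scale varies with age (younger
    # children show more labile glycemia), SD with HbA1c
    ar1_coeff_5min: float = 0.95
    ar1_age_slope: float = 0.012  # per year of age
    ar1_bounds: tuple[float, float] = (0.90, 0.98)
    process_noise_sd: float = 1.0  # stationary SD of the AR(1) term
    noise_hba1c_slope: float = 0.2  # relative SD change per % HbA1c
    noise_sd_bounds: tuple[float, float] = (0.6, 1.6)
    sensor_noise_sd: float = 0.3
    meter_noise_sd: float = 0.2
    # observation process
    scans_per_day: float = 8.0
    duplicate_fraction: float = 0.04
    symptom_threshold: float = 4.5
    symptom_prob: float = 0.3  # per 15-min block below threshold
    rescue_threshold: float = 3.6
    rescue_grams: float = 15.0
    rescue_refractory_min: float = 45.0


DEFAULT_PARAMS = GeneratorParams()


@dataclass
class Trajectory:
    """Latent glucose at 1-min resolution, mmol/l."""

    start: pd.Timestamp
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(np.arange(len(self.values)), unit="min")

    def at(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        idx = ((timestamps - self.start) / pd.Timedelta(minutes=1)).astype(int)
        idx = np.clip(idx, 0, len(self.values) - 1)
        return self.values[idx]


@dataclass
class EventPlan:
    """Concrete dosed/logged events, minutes from trajectory start."""

    carbs: list[tuple[float, float, str]] = field(default_factory=list)  # (min, g, type)
    insulin: list[tuple[float, float, str]] = field(default_factory=list)  # (min, IE, kind)
    activity: list[tuple[float, float, float]] = field(default_factory=list)  # (min, dur, intensity)


# ---------------------------------------------------------------------------
# static characteristics


def sample_statics(
    n_participants: int, seed: int, *, rng: np.random.Generator | None = None
) -> list[ParticipantStatics]:
    """Draw a cohort of static characteristics from the population model.

    Each numeric field follows a truncated normal with the reference-cohort
    mean/SD, truncated at the reference range; BMI is recomputed from the
    sampled weight and height (height is re-drawn with the weight until the
    implied BMI is anatomically plausible). Deterministic given ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw(name: str) -> float:
        mean, sd, low, high = STATIC_DISTRIBUTIONS[name]
        a, b = (low - mean) / sd, (high - mean) / sd
        return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))

    cohort: list[ParticipantStatics] = []
    for i in range(n_participants):
        age = draw("age")
        # joint weight/height draw, rejected until BMI lands in a sane band
        for _ in range(200):
            weight = draw("weight")
            height = draw("height")
            bmi = weight / (height / 100.0) ** 2
            if 12.0 <= bmi <= 30.0:
                break
        ctdd = draw("calculated_total_daily_dose")
        basal_pct = draw("basal_insulin_pct")
        tdd_ie = ctdd * weight
        cohort.append(
            ParticipantStatics(
                participant_id=f"SYN-{i + 1:03d}",
                gender=float(rng.random() < FEMALE_FRACTION),
                age=age,
                weight=weight,
                height=height,
                bmi=bmi,
                diabetes_duration=draw("diabetes_duration"),
                hba1c=draw("hba1c"),
                basal_insulin_pct=basal_pct,
                total_daily_basal=basal_pct / 100.0 * tdd_ie,
                total_daily_dose=ctdd,
                calculated_total_daily_dose=ctdd,
            )
        )
    return cohort


def insulin_sensitivity_gain(statics: ParticipantStatics) -> float:
    """Static insulin-sensitivity multiplier.

    Monotone increasing in age, decreasing in BMI, mildly increasing in the
    basal-insulin share; clipped to [0.4, 1.6]. Chosen so that the statics
    carry exploitable signal about each child's glucose dynamics.
    """
    g = (
        1.0
        + 0.09 * (statics.age - 11.2)
        - 0.02 * (statics.bmi - 19.5)
        + 0.006 * (statics.basal_insulin_pct - 46.1)
    )
    return float(np.clip(g, 0.4, 1.6))


# ---------------------------------------------------------------------------
# schedule and event planning


def default_camp_schedule(n_days: int = 6) -> CampSchedule:
    """Camp timetable: day 1 is a single outing; days 2-6 carry structured
    morning and afternoon sport sessions; a fixed daily meal pattern."""
    sessions: list[ActivitySession] = [ActivitySession(0, 11.0, 90.0, 1.0)]
    for d in range(1, min(n_days, 6)):
        sessions.append(ActivitySession(d, 10.0, 60.0, 1.0))
        sessions.append(ActivitySession(d, 14.0, 60.0, 1.0))
    meals = (
        MealSlot(7.5, 50.0, "mixed"),
        MealSlot(10.0 - 0.25, 15.0, "fast"),
        MealSlot(12.5, 70.0, "mixed"),
        MealSlot(16.0, 20.0, "slow"),
        MealSlot(18.5, 60.0, "mixed"),
        MealSlot(21.5, 15.0, "slow"),
    )
    return CampSchedule(
        n_days=n_days, activity_sessions=tuple(sessions), meal_slots=meals
    )


def plan_events(
    statics: ParticipantStatics,
    schedule: CampSchedule,
    seed: int,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> EventPlan:
    """Turn the camp schedule into concrete, jittered logbook events.

    Meal sizes scale sublinearly with body weight; meal boluses follow the
    500-rule carbohydrate ratio on the child's total daily dose; long-acting
    insulin is dosed once daily at 21:00 as the basal share of the total
    daily dose.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    plan = EventPlan()
    tdd_ie = max(statics.calculated_total_daily_dose * statics.weight, 5.0)
    icr = 500.0 / tdd_ie  # grams covered per IE
    for d in range(schedule.n_days):
        day0 = d * 24 * 60.0
        for slot in schedule.meal_slots:
            t = day0 + slot.hour * 60.0 + rng.uniform(-10.0, 10.0)
            grams = slot.grams * (statics.weight / 45.0) ** 0.8
            grams *= rng.uniform(0.85, 1.15)
            plan.carbs.append((t, grams, slot.absorption))
            if slot.absorption in ("mixed", "fast") and grams >= 10.0:
                dose = round(2.0 * grams / icr) / 2.0  # rounded to 0.5 IE
                if dose > 0:
                    plan.insulin.append((t + rng.uniform(-5.0, 5.0), dose, "short"))
        long_dose = round(2.0 * statics.total_daily_basal) / 2.0
        if long_dose > 0:
            plan.insulin.append((day0 + 21.0 * 60.0, long_dose, "long"))
        for sess in schedule.sessions_on(d):
            dur = sess.duration_min * rng.uniform(0.8, 1.2)
            inten = sess.intensity * rng.uniform(0.8, 1.2)
            plan.activity.append((day0 + sess.start_hour * 60.0, dur, inten))
    plan.carbs.sort()
    plan.insulin.sort()
    plan.activity.sort()
    return plan


# ---------------------------------------------------------------------------
# latent dynamics


def _lognormal_kernel(tpeak: float, sigma: float, length: int) -> np.ndarray:
    """Peak-normalised log-normal impulse response on a 1-min grid."""
    tau = np.arange(1, length + 1, dtype=float)
    mu = math.log(tpeak) + sigma**2  # mode of a log-normal = exp(mu - sigma^2)
    k = np.exp(-((np.log(tau) - mu) ** 2) / (2.0 * sigma**2)) / tau
    return k / k.max()


def _circadian_baseline(
    minutes: np.ndarray, statics: ParticipantStatics, params: GeneratorParams
) -> np.ndarray:
    hours = (minutes / 60.0) % 24.0
    level = params.base_level + params.hba1c_level_slope * (statics.hba1c - 7.2)
    amp = params.dawn_amplitude + params.dawn_age_slope * (statics.age - 11.2)
    # wrapped-gaussian dawn bump
    dh = (hours - params.dawn_hour + 12.0) % 24.0 - 12.0
    baseline = level + amp * np.exp(-0.5 * (dh / params.dawn_width_h) ** 2)
    # sustained offset from long-acting basal insulin
    baseline -= (
        params.long_insulin_rate
        * statics.total_daily_basal
        * insulin_sensitivity_gain(statics)
    )
    return baseline


def _sensitivity_series(
    n: int, plan: EventPlan, statics: ParticipantStatics, params: GeneratorParams
) -> np.ndarray:
    """S(t): static gain times (1 + activity-triggered elevation)."""
    elev = np.zeros(n)
    t = np.arange(n, dtype=float)
    for start, dur, inten in plan.activity:
        end = start + dur
        mask = t >= end
        elev[mask] += (
            params.sensitivity_elevation
            * inten
            * (dur / 60.0)
            * np.exp(-(t[mask] - end) / params.sensitivity_decay_min)
        )
    return insulin_sensitivity_gain(statics) * (1.0 + elev)


def _add_impulses(
    out: np.ndarray, events: list[tuple[float, float]], kernel: np.ndarray
) -> None:
    n = len(out)
    for t0, amplitude in events:
        i = int(round(t0))
        if i >= n:
            continue
        if i < 0:
            kern = kernel[-i:]
            i = 0
        else:
            kern = kernel
        m = min(len(kern), n - i)
        out[i : i + m] += amplitude * kern[:m]


def _ar1_noise(
    n: int,
    rng: np.random.Generator,
    statics: ParticipantStatics,
    params: GeneratorParams,
) -> np.ndarray:
    rho5 = float(
        np.clip(
            params.ar1_coeff_5min + params.ar1_age_slope * (statics.age - 11.2),
            *params.ar1_bounds,
        )
    )
    sd = float(
        np.clip(
            params.process_noise_sd
            * (1.0 + params.noise_hba1c_slope * (statics.hba1c - 7.2)),
            *params.noise_sd_bounds,
        )
    )
    rho = rho5 ** (1.0 / 5.0)  # per-minute coefficient
    innov_sd = sd * math.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    noise = np.empty(n)
    x = rng.normal(0.0, sd)
    for i in range(n):
        x = rho * x + eps[i]
        noise[i] = x
    return noise


def simulate_scenario(
    statics: ParticipantStatics,
    schedule: CampSchedule,
    seed: int,
    *,
    events: EventPlan | None = None,
    params: GeneratorParams = DEFAULT_PARAMS,
    noise: bool = True,
    rescue: bool = False,
    margin_min: float = 30.0,
) -> tuple[Trajectory, EventPlan]:
    """Run the latent model; returns the trajectory and the realised events
    (including any hypoglycemia rescue carbs when ``rescue`` is on).

    The trajectory spans from 06:30 of camp day 1 to 07:30 after the last
    scheduled day so that downstream interpolation has support at both ends
    of the anchored study window.
    """
    if events is None:
        events = plan_events(statics, schedule, seed, params)
    start = CAMP_START + pd.Timedelta(hours=6.5) - pd.Timedelta(minutes=margin_min)
    offset = 6.5 * 60.0 - margin_min  # planned-event clock minute 0 = midnight day 1
    n = int(schedule.n_days * 24 * 60 + 60 + 2 * margin_min)
    minutes = offset + np.arange(n, dtype=float)

    klen = 10 * 60
    sig = params.kernel_sigma
    kc = {
        "fast": _lognormal_kernel(params.tpeak_carb_fast, sig, klen),
        "mixed": _lognormal_kernel(params.tpeak_carb_mixed, sig, klen),
        "slow": _lognormal_kernel(params.tpeak_carb_slow, sig, klen),
    }
    ki_short = _lognormal_kernel(params.tpeak_insulin_short, sig, klen)
    ka = _lognormal_kernel(params.tpeak_activity, sig, klen)

    carb_gain = params.carb_gain_numerator / statics.weight
    tdd_ie = max(statics.calculated_total_daily_dose * statics.weight, 5.0)
    isf = params.isf_numerator / tdd_ie

    plan = EventPlan(
        carbs=list(events.carbs),
        insulin=list(events.insulin),
        activity=list(events.activity),
    )
    sens = _sensitivity_series(n, plan, statics, params)

    carb_dev = np.zeros(n)
    for kind in ("fast", "mixed", "slow"):
        _add_impulses(
            carb_dev,
            [(t - offset, g * carb_gain) for t, g, k in plan.carbs if k == kind],
            kc[kind],
        )
    ins_dev = np.zeros(n)
    _add_impulses(
        ins_dev,
        [(t - offset, d * isf) for t, d, k in plan.insulin if k == "short"],
        ki_short,
    )
    act_dev = np.zeros(n)
    for t0, dur, inten in plan.activity:
        occupancy = [
            (t0 - offset + m, inten * params.activity_gain)
            for m in range(0, int(round(dur)), 5)
        ]
        _add_impulses(act_dev, [(t, 5.0 * a) for t, a in occupancy], ka)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
    noise_dev = _ar1_noise(n, rng, statics, params) if noise else np.zeros(n)

    baseline = _circadian_baseline(minutes, statics, params)
    values = baseline + carb_dev - sens * ins_dev - act_dev + noise_dev

    if rescue:
        rescue_rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 31])
        )
        kern = kc["fast"]
        last_rescue = -1e9
        for i in range(n):
            if values[i] < params.rescue_threshold and i - last_rescue >= params.rescue_refractory_min:
                grams = params.rescue_grams * rescue_rng.uniform(0.9, 1.1)
                m = min(len(kern), n - i - 1)
                values[i + 1 : i + 1 + m] += grams * carb_gain * kern[:m]
                plan.carbs.append((float(minutes[i]), grams, "fast"))
                last_rescue = i
        plan.carbs.sort()

    values = np.clip(values, 1.0, SENSOR_MAX_MMOL - 1e-9)
    return Trajectory(start=start, values=values), plan


def simulate_glucose_dynamics(
    statics: ParticipantStatics,
    schedule: CampSchedule,
    seed: int,
    *,
    events: EventPlan | None = None,
    params: GeneratorParams = DEFAULT_PARAMS,
    noise: bool = True,
) -> Trajectory:
    """Latent glucose trajectory at 1-min resolution (no rescue feedback)."""
    traj, _ = simulate_scenario(
        statics, schedule, seed, events=events, params=params, noise=noise
    )
    return traj


# ---------------------------------------------------------------------------
# observation process


def _event_timestamp(traj: Trajectory, clock_min: float) -> pd.Timestamp:
    return CAMP_START + pd.Timedelta(minutes=float(clock_min))


def emit_streams(
    trajectory: Trajectory,
    statics: ParticipantStatics,
    schedule: CampSchedule,
    device_kind: DeviceKind | str,
    seed: int,
    *,
    events: EventPlan | None = None,
    params: GeneratorParams = DEFAULT_PARAMS,
    sensor_noise: bool = True,
) -> RawStreams:
    """Observe a latent trajectory through sensor and logbook.

    Sensor records sample the trajectory at device cadence with additive
    noise (isCGM additionally at irregular scan times); SMBG records are
    emitted at the protocol triggers — sensor below 3.9 mmol/l, sensor above
    15 mmol/l, before and after each activity session, hourly during
    sessions, plus symptom-driven checks when latent glucose is below
    4.5 mmol/l — with independent meter noise. A configurable fraction of
    duplicate sensor timestamps is injected to exercise downstream merging.
    """
    device_kind = DeviceKind(device_kind)
    if events is None:
        events = plan_events(statics, schedule, seed, params)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 47]))

    cadence_min = int(device_kind.cadence / pd.Timedelta(minutes=1))
    n = len(trajectory)
    times = trajectory.times()

    def observe(idx: np.ndarray, sd: float) -> np.ndarray:
        vals = trajectory.values[idx]
        if sensor_noise and sd > 0:
            vals = vals + rng.normal(0.0, sd, size=len(idx))
        return np.clip(vals, 1.0, SENSOR_MAX_MMOL)

    sensor_idx = np.arange(0, n, cadence_min)
    sensor_vals = observe(sensor_idx, params.sensor_noise_sd)
    sensor_times = list(times[sensor_idx])
    sensor_values = list(sensor_vals)

    if device_kind is DeviceKind.ISCGM_15MIN and params.scans_per_day > 0:
        n_days = max(n / (24 * 60.0), 1e-9)
        n_scans = rng.poisson(params.scans_per_day * n_days)
        if n_scans > 0:
            scan_idx = np.sort(rng.integers(0, n, size=n_scans))
            # scans happen while awake (07:00-22:00 local clock)
            hours = ((scan_idx + (times[0].hour * 60 + times[0].minute)) / 60.0) % 24
            scan_idx = scan_idx[(hours >= 7.0) & (hours <= 22.0)]
            scan_vals = observe(scan_idx, params.sensor_noise_sd)
            sensor_times.extend(times[scan_idx])
            sensor_values.extend(scan_vals)

    # duplicate-timestamp injection (same timestamp, perturbed value)
    if params.duplicate_fraction > 0 and len(sensor_times) > 0:
        k = int(params.duplicate_fraction * len(sensor_times))
        if k > 0:
            pick = rng.choice(len(sensor_times), size=k, replace=False)
            for j in pick:
                sensor_times.append(sensor_times[j])
                sensor_values.append(
                    float(np.clip(sensor_values[j] + abs(rng.normal(0.0, 0.4)), 1.0, SENSOR_MAX_MMOL))
                )

    sensor = pd.DataFrame({"timestamp": sensor_times, "glucose": sensor_values})
    sensor = sensor.sort_values("timestamp", kind="stable").reset_index(drop=True)

    # --- SMBG triggers -----------------------------------------------------
    smbg_times: list[pd.Timestamp] = []

    def meter(ts_list: list[pd.Timestamp]) -> None:
        smbg_times.extend(ts_list)

    low_high = sensor[(sensor["glucose"] < 3.9) | (sensor["glucose"] > 15.0)]
    meter(list(low_high["timestamp"]))

    offset_min = (trajectory.start - CAMP_START) / pd.Timedelta(minutes=1)
    for t0, dur, _ in events.activity:
        start_ts = CAMP_START + pd.Timedelta(minutes=t0)
        end_ts = start_ts + pd.Timedelta(minutes=dur)
        session = [start_ts, end_ts]  # before and after
        h = 60.0
        while h < dur:
            session.append(start_ts + pd.Timedelta(minutes=h))
            h += 60.0
        meter([ts for ts in session if times[0] <= ts <= times[-1]])

    # symptom-driven checks: Bernoulli per 15-min block with low latent glucose
    block = 15
    for i in range(0, n - block, block):
        if trajectory.values[i] < params.symptom_threshold and rng.random() < params.symptom_prob:
            meter([times[i + int(rng.integers(0, block))]])

    smbg_times = sorted(set(smbg_times))
    smbg_idx = np.array(
        [(ts - trajectory.start) // pd.Timedelta(minutes=1) for ts in smbg_times],
        dtype=int,
    )
    smbg_vals = (
        observe(smbg_idx, params.meter_noise_sd) if len(smbg_idx) else np.array([])
    )
    smbg = pd.DataFrame({"timestamp": smbg_times, "glucose": smbg_vals})

    def in_span(ts: pd.Timestamp) -> bool:
        return times[0] <= ts <= times[-1]

    insulin = pd.DataFrame(
        [
            {"timestamp": _event_timestamp(trajectory, t), "dose": d, "kind": k}
            for t, d, k in events.insulin
            if in_span(_event_timestamp(trajectory, t))
        ],
        columns=["timestamp", "dose", "kind"],
    )
    carbs = pd.DataFrame(
        [
            {"timestamp": _event_timestamp(trajectory, t), "grams": g, "absorption": k}
            for t, g, k in events.carbs
            if in_span(_event_timestamp(trajectory, t))
        ],
        columns=["timestamp", "grams", "absorption"],
    )
    activity = pd.DataFrame(
        [
            {"timestamp": _event_timestamp(trajectory, t), "duration": d}
            for t, d, _ in events.activity
            if in_span(_event_timestamp(trajectory, t))
        ],
        columns=["timestamp", "duration"],
    )

    return RawStreams(
        participant_id=statics.participant_id,
        device_kind=device_kind,
        sensor=sensor,
        smbg=smbg,
        insulin=insulin,
        carbs=carbs,
        activity=activity,
    )


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    n_participants: int = 14,
    n_days: int = 6,
    seed: int = 0,
    *,
    outdir=None,
    params: GeneratorParams = DEFAULT_PARAMS,
    truncate_one: bool = True,
) -> tuple[list[RawStreams], list[ParticipantStatics]]:
    """Generate a full camp cohort of raw streams plus the statics table.

    Device mix follows the study cohort (9 isCGM : 5 CGM out of 14). When
    ``truncate_one`` and the camp is long enough, one participant's streams
    are truncated to the final four study days. If ``outdir`` is given the
    cohort is written as delimited text files that round-trip through
    :mod:`glucast.io`.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    cohort_rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 5]))
    statics = sample_statics(n_participants, seed, rng=cohort_rng)
    schedule = default_camp_schedule(n_days)
    n_iscgm = int(round(ISCGM_FRACTION * n_participants))

    streams: list[RawStreams] = []
    truncate_idx = n_participants - 2 if (truncate_one and n_days >= 5 and n_participants > 1) else -1
    for i, st in enumerate(statics):
        pseed = int(cohort_rng.integers(0, 2**31 - 1))
        traj, events = simulate_scenario(
            st, schedule, pseed, params=params, rescue=True
        )
        device = DeviceKind.ISCGM_15MIN if i < n_iscgm else DeviceKind.CGM_5MIN
        raw = emit_streams(
            traj, st, schedule, device, pseed, events=events, params=params
        )
        if i == truncate_idx:
            cut = CAMP_START + pd.Timedelta(days=n_days - 4, hours=6, minutes=30)
            for attr in ("sensor", "smbg", "insulin", "carbs", "activity"):
                df = getattr(raw, attr)
                setattr(raw, attr, df[df["timestamp"] >= cut].reset_index(drop=True))
        streams.append(raw)

    if outdir is not None:
        from . import io as gio

        gio.write_cohort(outdir, streams, statics)
    return streams, statics


__all__ = [
    "CAMP_START",
    "DEFAULT_PARAMS",
    "GeneratorParams",
    "Trajectory",
    "EventPlan",
    "sample_statics",
    "insulin_sensitivity_gain",
    "default_camp_schedule",
    "plan_events",
    "simulate_scenario",
    "simulate_glucose_dynamics",
    "emit_streams",
    "generate_cohort",
]
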