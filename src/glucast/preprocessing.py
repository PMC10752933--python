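"""Merging, regularisation and chronological splitting of raw streams.

The pipeline per participant is: merge sensor and SMBG glucose into a single
deduplicated measurement list (SMBG overrides the sensor at identical
timestamps; among residual duplicates the lower value is kept), resample
everything onto a gapless 5-min grid — glucose by time-weighted linear
interpolation, events by summation into the preceding 5-min window — clip to
anchored study days (7:00 a.m. to 6:55 a.m.), and split chronologically into
train / validation / test with the last 16.66% as the test day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    DAY_ANCHOR_HOUR,
    FEATURES,
    GRID_STEP,
    POINTS_PER_DAY,
    RawStreams,
    RegularSeries,
    SplitSeries,
    Standardizer,
)

logger = logging.getLogger(__name__)

#: Sensor dropouts longer than this are logged for audit.
GAP_AUDIT_THRESHOLD = pd.Timedelta(hours=1)


class GridExtrapolationError(ValueError):
    """A requested grid time lies outside the glucose measurement hull by
    more than one device cadence; extrapolation is forbidden."""


@dataclass
class MergedStreams:
    """Deduplicated glucose measurements plus pass-through logbook events."""

    participant_id: str
    glucose: pd.DataFrame  # columns: timestamp, glucose (one row per timestamp)
    insulin: pd.DataFrame
    carbs: pd.DataFrame
    activity: pd.DataFrame
    cadence: pd.Timedelta


def merge_streams(raw: RawStreams) -> MergedStreams:
    """Merge sensor and SMBG glucose into one value per timestamp.

    At sensor/SMBG timestamp collisions the SMBG value wins; among residual
    duplicate timestamps the lower glucose measurement is kept. Non-glucose
    events pass through unchanged.
    """
    if raw.sensor is None or len(raw.sensor) == 0:
        raise ValueError(f"empty sensor stream for {raw.participant_id}")
    for name, df in (("sensor", raw.sensor), ("smbg", raw.smbg)):
        if len(df) and (df["glucose"] <= 0).any():
            raise ValueError(f"non-positive glucose value in {name} stream")

    sensor = raw.sensor.assign(source="sensor")
    smbg = raw.smbg.assign(source="smbg") if len(raw.smbg) else None
    frames = [sensor] if smbg is None else [sensor, smbg]
    merged = pd.concat(frames, ignore_index=True)

    # SMBG overrides sensor at identical timestamps: drop sensor rows whose
    # timestamp also carries an SMBG record, then keep the minimum among the
    # remaining duplicates.
    if smbg is not None:
        smbg_ts = set(smbg["timestamp"])
        keep = (merged["source"] == "smbg") | ~merged["timestamp"].isin(smbg_ts)
        merged = merged[keep]
    merged = (
        merged.groupby("timestamp", as_index=False)["glucose"]
        .min()
        .sort_values("timestamp", kind="stable")
        .reset_index(drop=True)
    )
    return MergedStreams(
        participant_id=raw.participant_id,
        glucose=merged,
        insulin=raw.insulin.copy(),
        carbs=raw.carbs.copy(),
        activity=raw.activity.copy(),
        cadence=raw.device_kind.cadence,
    )


def _interpolate_glucose(
    meas_ts: np.ndarray, meas_val: np.ndarray, grid_ns: np.ndarray, cadence: pd.Timedelta
) -> np.ndarray:
    """Time-weighted linear interpolation onto the grid.

    Grid times outside the measurement hull take the nearest measurement's
    value when within one device cadence of the hull; beyond that the grid is
    rejected (the caller should trim the series instead).
    """
    lo, hi = meas_ts[0], meas_ts[-1]
    slack = cadence.value
    if grid_ns[0] < lo - slack or grid_ns[-1] > hi + slack:
        raise GridExtrapolationError(
            "grid extends beyond the glucose measurement hull by more than "
            "one device cadence"
        )
    return np.interp(grid_ns.astype(float), meas_ts.astype(float), meas_val)


def _sum_to_next_stamp(
    events: pd.DataFrame, value_col: str, grid: pd.DatetimeIndex
) -> np.ndarray:
    """Sum event values into the half-open window (t - 5 min, t] per grid t."""
    out = np.zeros(len(grid))
    if events is None or len(events) == 0:
        return out
    start_ns = grid[0].value - GRID_STEP.value
    step = GRID_STEP.value
    ts = events["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    vals = events[value_col].to_numpy(dtype=float)
    # index of the next grid stamp: ceil((ts - start) / step) - 1 into grid
    pos = np.ceil((ts - start_ns) / step).astype(int) - 1
    ok = (pos >= 0) & (pos < len(grid))
    np.add.at(out, pos[ok], vals[ok])
    return out


def _spread_activity(activity: pd.DataFrame, grid: pd.DatetimeIndex) -> np.ndarray:
    """Spread each session over its covered grid steps, min(5, remaining)
    minutes per step, so the activity feature sums to the session duration."""
    out = np.zeros(len(grid))
    if activity is None or len(activity) == 0:
        return out
    start_ns = grid[0].value - GRID_STEP.value
    step = GRID_STEP.value
    for _, row in activity.iterrows():
        remaining = float(row["duration"])
        ts = pd.Timestamp(row["timestamp"]).value
        pos = int(np.ceil((ts - start_ns) / step)) - 1
        while remaining > 0 and pos < len(grid):
            if pos >= 0:
                out[pos] += min(5.0, remaining)
            remaining -= 5.0
            pos += 1
    return out


def resample_to_grid(
    merged: MergedStreams,
    start: pd.Timestamp,
    end: pd.Timestamp,
) -> RegularSeries:
    """Resample merged streams onto the gapless 5-min grid [start, end].

    Glucose at each grid time is the time-weighted linear interpolation of
    the bracketing measurements; insulin, carb and activity features are
    summed into the preceding 5-min window ("assigned to the next time
    stamp"); grid times without events carry zero.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start >= end:
        raise ValueError("start must precede end")
    if len(merged.glucose) < 2:
        raise ValueError("need at least two glucose measurements")

    grid = pd.date_range(start, end, freq=GRID_STEP)
    meas_ts = merged.glucose["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    meas_val = merged.glucose["glucose"].to_numpy(dtype=float)

    gaps = np.diff(meas_ts)
    long_gaps = np.nonzero(gaps > GAP_AUDIT_THRESHOLD.value)[0]
    for i in long_gaps:
        logger.warning(
            "%s: sensor gap of %s starting %s — interpolated across",
            merged.participant_id,
            pd.Timedelta(int(gaps[i]), unit="ns"),
            pd.Timestamp(int(meas_ts[i])),
        )

    glucose = _interpolate_glucose(meas_ts, meas_val, grid.asi8, merged.cadence)

    insulin = merged.insulin
    short = insulin[insulin["kind"] == "short"] if len(insulin) else insulin
    long_ = insulin[insulin["kind"] == "long"] if len(insulin) else insulin
    carbs = merged.carbs

    def carb_type(kind: str) -> pd.DataFrame:
        return carbs[carbs["absorption"] == kind] if len(carbs) else carbs

    frame = pd.DataFrame(
        {
            "glucose": glucose,
            "short_insulin": _sum_to_next_stamp(short, "dose", grid),
            "long_insulin": _sum_to_next_stamp(long_, "dose", grid),
            "activity": _spread_activity(merged.activity, grid),
            "carbs_fast": _sum_to_next_stamp(carb_type("fast"), "grams", grid),
            "carbs_slow": _sum_to_next_stamp(carb_type("slow"), "grams", grid),
            "carbs_mixed": _sum_to_next_stamp(carb_type("mixed"), "grams", grid),
        },
        index=grid,
    )
    return RegularSeries(participant_id=merged.participant_id, frame=frame)


def clip_study_window(
    series: RegularSeries, day_anchor_hour: int = DAY_ANCHOR_HOUR
) -> RegularSeries:
    """Clip to whole anchored days: from the first ``day_anchor_hour``:00
    with data to (anchor − 5 min) of the final day; length becomes a
    multiple of 288."""
    idx = series.frame.index
    anchored = np.nonzero((idx.hour == day_anchor_hour) & (idx.minute == 0))[0]
    if len(anchored) == 0:
        raise ValueError("series does not reach the day anchor")
    first = int(anchored[0])
    n_days = (len(series) - first) // POINTS_PER_DAY
    if n_days < 1:
        raise ValueError("less than one full anchored day of coverage")
    return series.slice(first, first + n_days * POINTS_PER_DAY)


def split_train_val_test(
    series: RegularSeries, fraction: float = 0.1666
) -> SplitSeries:
    """Chronological split: the last ``round(fraction * T)`` points are the
    test set (a full day for a 6-day series), the preceding equal-size block
    is validation, the remainder is training. The feature standardizer is
    fitted on the training segment only."""
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    total = len(series)
    n_test = int(round(fraction * total))
    if n_test < 1 or total - 2 * n_test < 1:
        raise ValueError(f"series of length {total} too short to split")
    train = series.slice(0, total - 2 * n_test)
    validation = series.slice(total - 2 * n_test, total - n_test)
    test = series.slice(total - n_test, total)
    standardizer = Standardizer.fit(train.values())
    return SplitSeries(
        train=train, validation=validation, test=test, standardizer=standardizer
    )


def preprocess_participant(raw: RawStreams, fraction: float = 0.1666) -> SplitSeries:
    """Full per-participant pipeline: merge, resample, clip, split."""
    merged = merge_streams(raw)
    start = merged.glucose["timestamp"].iloc[0].ceil("5min")
    end = merged.glucose["timestamp"].iloc[-1].floor("5min")
    series = resample_to_grid(merged, start, end)
    return split_train_val_test(clip_study_window(series), fraction)


__all__ = [
    "GridExtrapolationError",
    "MergedStreams",
    "merge_streams",
    "resample_to_grid",
    "clip_study_window",
    "split_train_val_test",
    "preprocess_participant",
]
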