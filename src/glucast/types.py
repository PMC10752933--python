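"""Core domain containers shared across the pipeline.

Glucose is carried in mmol/l throughout; insulin doses in IE (international
units), carbohydrates in grams, physical activity in minutes. Timestamps are
timezone-naive local clock times: the study setting is single-site and the
day anchor (7 a.m.) is a local clock convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the seven time-varying features.
FEATURES = (
    "glucose",
    "short_insulin",
    "long_insulin",
    "activity",
    "carbs_fast",
    "carbs_slow",
    "carbs_mixed",
)

#: Names of the eleven static participant characteristics, in table order.
STATIC_FIELDS = (
    "gender",
    "age",
    "weight",
    "height",
    "bmi",
    "diabetes_duration",
    "hba1c",
    "basal_insulin_pct",
    "total_daily_basal",
    "total_daily_dose",
    "calculated_total_daily_dose",
)

#: The hand-selected six-feature subset of the static characteristics.
STATIC_SUBSET_6 = (
    "gender",
    "age",
    "weight",
    "bmi",
    "diabetes_duration",
    "basal_insulin_pct",
)

#: Upper saturation limit of the glucose sensors (mmol/l).
SENSOR_MAX_MMOL = 33.3

#: Grid step of the regularised series.
GRID_STEP = pd.Timedelta(minutes=5)

#: Points per anchored study day (24 h at 5-min cadence).
POINTS_PER_DAY = 288

#: Local clock hour at which a study day starts.
DAY_ANCHOR_HOUR = 7


class DeviceKind(str, enum.Enum):
    """Glucose sensor type: real-time CGM (5-min) or intermittently scanned
    CGM (15-min plus user-initiated scans)."""

    CGM_5MIN = "CGM_5min"
    ISCGM_15MIN = "isCGM_15min"

    @property
    def cadence(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=5 if self is DeviceKind.CGM_5MIN else 15)


@dataclass(frozen=True)
class ParticipantStatics:
    """Static characteristics of one child.

    ``gender`` is coded 1.0 for female, 0.0 for male. ``basal_insulin_pct``
    is the basal share of the total daily insulin dose in percent;
    ``total_daily_basal`` is in IE/day, the two total-daily-dose fields in
    U/kg/day.
    """

    participant_id: str
    gender: float
    age: float
    weight: float
    height: float
    bmi: float
    diabetes_duration: float
    hba1c: float
    basal_insulin_pct: float
    total_daily_basal: float
    total_daily_dose: float
    calculated_total_daily_dose: float

    def __post_init__(self) -> None:
        values = [getattr(self, f) for f in STATIC_FIELDS]
        if not all(np.isfinite(values)):
            raise ValueError(f"non-finite static field for {self.participant_id}")
        if not 7.0 <= self.age <= 16.0:
            raise ValueError(f"age {self.age} outside the 7-16 y inclusion range")
        if not 0.0 < self.basal_insulin_pct < 100.0:
            raise ValueError("basal_insulin_pct must lie in (0, 100)")
        expected_bmi = self.weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 0.1:
            raise ValueError(
                f"bmi {self.bmi:.2f} inconsistent with weight/height "
                f"(expected {expected_bmi:.2f})"
            )

    def vector(self, subset: str = "all") -> np.ndarray:
        """Static feature vector: ``subset`` is ``'all'`` (11) or ``'six'``."""
        names = STATIC_FIELDS if subset == "all" else STATIC_SUBSET_6
        return np.array([getattr(self, n) for n in names], dtype=float)


@dataclass(frozen=True)
class ActivitySession:
    day: int  # 0-based study-day index
    start_hour: float  # local clock hours, e.g. 10.5 = 10:30
    duration_min: float
    intensity: float  # dimensionless, ~1 for moderate exercise


@dataclass(frozen=True)
class MealSlot:
    hour: float  # local clock hours
    grams: float
    absorption: str  # 'fast' | 'slow' | 'mixed'


@dataclass(frozen=True)
class CampSchedule:
    """Camp timetable: structured morning/afternoon sport on days 2-6 and a
    fixed meal pattern every day."""

    n_days: int
    activity_sessions: tuple[ActivitySession, ...]
    meal_slots: tuple[MealSlot, ...]

    def sessions_on(self, day: int) -> list[ActivitySession]:
        return [s for s in self.activity_sessions if s.day == day]


@dataclass
class RawStreams:
    """Unmerged sensor readings and logbook events for one participant.

    ``sensor`` has columns (timestamp, glucose); ``smbg`` likewise;
    ``insulin`` (timestamp, dose, kind in {short, long}); ``carbs``
    (timestamp, grams, absorption in {fast, slow, mixed}); ``activity``
    (timestamp, duration).
    """

    participant_id: str
    device_kind: DeviceKind
    sensor: pd.DataFrame
    smbg: pd.DataFrame
    insulin: pd.DataFrame
    carbs: pd.DataFrame
    activity: pd.DataFrame


@dataclass
class RegularSeries:
    """One participant's 7-feature series on a gapless 5-min grid."""

    participant_id: str
    frame: pd.DataFrame  # index: DatetimeIndex at 5-min; columns: FEATURES

    def __post_init__(self) -> None:
        missing = [c for c in FEATURES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        self.frame = self.frame[list(FEATURES)]
        idx = self.frame.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not np.all(deltas == GRID_STEP.value):
                raise ValueError("grid is not gapless at 5-min spacing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start(self) -> pd.Timestamp:
        return self.frame.index[0]

    @property
    def glucose(self) -> np.ndarray:
        return self.frame["glucose"].to_numpy()

    def values(self) -> np.ndarray:
        """(T, 7) float array in canonical feature order."""
        return self.frame.to_numpy(dtype=float)

    def slice(self, start: int, stop: int) -> "RegularSeries":
        return RegularSeries(self.participant_id, self.frame.iloc[start:stop])


@dataclass(frozen=True)
class Standardizer:
    """Per-feature affine transform fitted on a training segment."""

    mean: np.ndarray  # (7,)
    std: np.ndarray  # (7,)

    @classmethod
    def fit(cls, values: np.ndarray) -> "Standardizer":
        mean = values.mean(axis=0)
        std = values.std(axis=0)
        std = np.where(std > 0, std, 1.0)  # constant features pass through
        return cls(mean=mean, std=std)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    def inverse_glucose(self, z: np.ndarray) -> np.ndarray:
        g = FEATURES.index("glucose")
        return z * self.std[g] + self.mean[g]

    def transform_glucose(self, y: np.ndarray) -> np.ndarray:
        g = FEATURES.index("glucose")
        return (y - self.mean[g]) / self.std[g]


@dataclass
class SplitSeries:
    """Chronological train/validation/test split of one participant's series,
    with the standardizer fitted on the training segment only."""

    train: RegularSeries
    validation: RegularSeries
    test: RegularSeries
    standardizer: Standardizer

    @property
    def participant_id(self) -> str:
        return self.train.participant_id


__all__ = [
    "FEATURES",
    "STATIC_FIELDS",
    "STATIC_SUBSET_6",
    "SENSOR_MAX_MMOL",
    "GRID_STEP",
    "POINTS_PER_DAY",
    "DAY_ANCHOR_HOUR",
    "DeviceKind",
    "ParticipantStatics",
    "ActivitySession",
    "MealSlot",
    "CampSchedule",
    "RawStreams",
    "RegularSeries",
    "Standardizer",
    "SplitSeries",
]
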