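"""Delimited-text interchange for cohort tables.

All tables are comma-separated UTF-8 with a header row and ISO-8601
timestamps. Unknown columns are preserved on read; malformed rows are
rejected with their line number.

Per-participant files inside a cohort directory::

    statics.csv                     one row per participant
    <pid>/sensor.csv                timestamp, glucose
    <pid>/smbg.csv                  timestamp, glucose
    <pid>/insulin.csv               timestamp, dose, kind
    <pid>/carbs.csv                 timestamp, grams, absorption
    <pid>/activity.csv              timestamp, duration
    <pid>/meta.csv                  device_kind
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import STATIC_FIELDS, DeviceKind, ParticipantStatics, RawStreams

_STREAM_SCHEMAS = {
    "sensor": {"timestamp": "datetime", "glucose": "positive"},
    "smbg": {"timestamp": "datetime", "glucose": "positive"},
    "insulin": {"timestamp": "datetime", "dose": "nonnegative", "kind": "str"},
    "carbs": {"timestamp": "datetime", "grams": "nonnegative", "absorption": "str"},
    "activity": {"timestamp": "datetime", "duration": "nonnegative"},
}


class TableFormatError(ValueError):
    """Malformed table: missing columns or invalid rows (with line context)."""


def _read_table(path: Path, schema: dict[str, str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise TableFormatError(f"{path}: file not found") from exc
    except Exception as exc:  # surfaced with file path context
        raise TableFormatError(f"{path}: unreadable ({exc})") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory columns {missing}")
    for col, kind in schema.items():
        if kind == "datetime":
            parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
            bad = np.nonzero(parsed.isna().to_numpy())[0]
            if len(bad):
                raise TableFormatError(
                    f"{path}, line {bad[0] + 2}: unparseable timestamp "
                    f"{df[col].iloc[bad[0]]!r}"
                )
            df[col] = parsed
        elif kind in ("positive", "nonnegative"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = np.nonzero(vals.isna().to_numpy())[0]
            if len(bad):
                raise TableFormatError(
                    f"{path}, line {bad[0] + 2}: non-numeric value "
                    f"{df[col].iloc[bad[0]]!r} in {col!r}"
                )
            limit = 0.0
            invalid = (vals <= limit) if kind == "positive" else (vals < limit)
            bad = np.nonzero(invalid.to_numpy())[0]
            if len(bad):
                raise TableFormatError(
                    f"{path}, line {bad[0] + 2}: {col!r} must be "
                    f"{'positive' if kind == 'positive' else 'non-negative'}, "
                    f"got {vals.iloc[bad[0]]}"
                )
            df[col] = vals.astype(float)
    return df


def write_streams(directory, raw: RawStreams) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("sensor", "smbg", "insulin", "carbs", "activity"):
        df = getattr(raw, name).copy()
        if len(df):
            df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            )
        df.to_csv(directory / f"{name}.csv", index=False)
    pd.DataFrame({"device_kind": [raw.device_kind.value]}).to_csv(
        directory / "meta.csv", index=False
    )


def read_streams(directory, participant_id: str | None = None) -> RawStreams:
    directory = Path(directory)
    meta = pd.read_csv(directory / "meta.csv")
    device = DeviceKind(meta["device_kind"].iloc[0])
    frames = {
        name: _read_table(directory / f"{name}.csv", schema)
        for name, schema in _STREAM_SCHEMAS.items()
    }
    return RawStreams(
        participant_id=participant_id or directory.name,
        device_kind=device,
        sensor=frames["sensor"],
        smbg=frames["smbg"],
        insulin=frames["insulin"],
        carbs=frames["carbs"],
        activity=frames["activity"],
    )


def write_statics(path, cohort: list[ParticipantStatics]) -> None:
    rows = [
        {"participant_id": st.participant_id, **{f: getattr(st, f) for f in STATIC_FIELDS}}
        for st in cohort
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_statics(path) -> list[ParticipantStatics]:
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", *STATIC_FIELDS) if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory columns {missing}")
    return [
        ParticipantStatics(
            participant_id=str(row["participant_id"]),
            **{f: float(row[f]) for f in STATIC_FIELDS},
        )
        for _, row in df.iterrows()
    ]


def write_cohort(directory, streams: list[RawStreams], statics: list[ParticipantStatics]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_statics(directory / "statics.csv", statics)
    for raw in streams:
        write_streams(directory / raw.participant_id, raw)


def read_cohort(directory) -> tuple[list[RawStreams], list[ParticipantStatics]]:
    directory = Path(directory)
    statics = read_statics(directory / "statics.csv")
    streams = [read_streams(directory / st.participant_id, st.participant_id) for st in statics]
    return streams, statics


__all__ = [
    "TableFormatError",
    "write_streams",
    "read_streams",
    "write_statics",
    "read_statics",
    "write_cohort",
    "read_cohort",
]
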