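"""Raw 10-second epoch streams to valid child-day percent-sedentary records.

The processing chain mirrors standard paediatric actigraphy practice for
wrist-worn count accelerometers:

1. ingest timestamped triaxial counts at 10-s resolution;
2. flag non-wear ("spurious") time as runs of >= 20 (or 30) consecutive
   minutes of zero counts on the x-axis (or on the vector magnitude);
3. remove non-wear and sleep; what remains is awake wear time;
4. dichotomise awake epochs at the wrist cut-point of <= 356 x-axis
   counts per 10-s epoch (sedentary vs active);
5. per calendar day, Y = 100 * sedentary / awake minutes;
6. keep days with >= 600 awake minutes and children with >= 3 valid
   weekdays and >= 1 valid weekend day (alternative strict profile:
   >= 720 minutes and >= 5 valid days).

Day boundaries are local civil midnight in the stream's timezone. A
single non-zero epoch breaks a zero run (no tolerance window), and runs
truncated by the stream edges still qualify if long enough.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

EPOCH_SECONDS = 10
EPOCHS_PER_MINUTE = 60 // EPOCH_SECONDS
#: Wrist cut-point for 4–6 year olds: sedentary iff x-count <= CUTPOINT per 10-s epoch.
CUTPOINT = 356

# wear-mask labels
WORN_AWAKE = 0
WORN_ASLEEP = 1
NONWEAR = 2

__all__ = [
    "EpochStream",
    "EpochStreamError",
    "CUTPOINT",
    "EPOCH_SECONDS",
    "WORN_AWAKE",
    "WORN_ASLEEP",
    "NONWEAR",
    "read_epoch_csv",
    "write_epoch_csv",
    "vector_magnitude",
    "detect_nonwear",
    "apply_sleep",
    "classify_epoch",
    "summarize_days",
    "filter_valid",
    "process_stream",
]


class EpochStreamError(ValueError):
    """Malformed or inconsistent epoch data."""


@dataclasses.dataclass
class EpochStream:
    """An ordered, duplicate-free triaxial count stream for one child.

    ``records`` has columns timestamp (naive local datetime on the 10-s
    grid), x, y, z (non-negative integer counts).
    """

    child_id: str
    records: pd.DataFrame
    timezone: str = "America/Mexico_City"

    def __post_init__(self):
        df = self.records.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        if df["timestamp"].duplicated().any():
            first = df.loc[df["timestamp"].duplicated(), "timestamp"].iloc[0]
            raise EpochStreamError(
                f"duplicate timestamp {first} in stream for child {self.child_id}"
            )
        for axis in ("x", "y", "z"):
            vals = pd.to_numeric(df[axis], errors="coerce")
            if vals.isna().any():
                row = int(np.argmax(vals.isna().to_numpy()))
                raise EpochStreamError(f"non-numeric {axis} count at row {row}")
            if (vals < 0).any():
                row = int(np.argmax((vals < 0).to_numpy()))
                raise EpochStreamError(f"negative {axis} count at row {row}")
            df[axis] = vals.astype(np.int64)
        self.records = df

    def __len__(self):
        return len(self.records)

    @property
    def timestamps(self) -> pd.Series:
        return self.records["timestamp"]

    def counts(self, axis: str) -> np.ndarray:
        return self.records[axis].to_numpy()


def read_epoch_csv(path, timezone: str = "America/Mexico_City") -> dict[str, EpochStream]:
    """Read the epoch-CSV dialect (header child_id,timestamp,x,y,z,
    ISO-8601 local timestamps) into one EpochStream per child.

    Rows may arrive out of order; duplicates or negative counts raise
    :class:`EpochStreamError`.
    """
    df = pd.read_csv(path)
    expected = ["child_id", "timestamp", "x", "y", "z"]
    if list(df.columns) != expected:
        raise EpochStreamError(f"expected header {expected}, got {list(df.columns)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise EpochStreamError(f"unparseable timestamp in {path}: {exc}") from exc
    return {
        str(cid): EpochStream(str(cid), group.drop(columns="child_id"), timezone)
        for cid, group in df.groupby("child_id", sort=True)
    }


def write_epoch_csv(streams, path) -> None:
    frames = []
    for stream in streams:
        df = stream.records.copy()
        df.insert(0, "child_id", stream.child_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def vector_magnitude(x, y, z):
    """Triaxial vector magnitude sqrt(x^2 + y^2 + z^2) per epoch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    return np.sqrt(x * x + y * y + z * z)


def _zero_runs(is_zero: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True with length >= min_len, as [i0, i1) index pairs."""
    padded = np.concatenate(([False], is_zero, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= min_len]


def detect_nonwear(
    stream: EpochStream,
    signal: Literal["x_axis", "vector_magnitude"] = "x_axis",
    min_run_minutes: int = 20,
) -> list[tuple[int, int]]:
    """Non-wear intervals as maximal zero-count runs.

    An interval is flagged iff the chosen signal is exactly zero for at
    least ``min_run_minutes * 6`` consecutive epochs. Returned as ordered,
    non-overlapping half-open epoch-index pairs ``(i0, i1)``.
    """
    if signal == "x_axis":
        sig = stream.counts("x").astype(float)
    elif signal == "vector_magnitude":
        sig = vector_magnitude(stream.counts("x"), stream.counts("y"), stream.counts("z"))
    else:
        raise ValueError(f"unknown non-wear signal {signal!r}")
    if min_run_minutes not in (20, 30):
        raise ValueError(f"min_run_minutes must be 20 or 30, got {min_run_minutes}")
    return _zero_runs(sig == 0.0, min_run_minutes * EPOCHS_PER_MINUTE)


def _interval_mask(timestamps: pd.Series, intervals: pd.DataFrame) -> np.ndarray:
    ts = timestamps.to_numpy()
    mask = np.zeros(len(ts), dtype=bool)
    for start, end in zip(
        pd.to_datetime(intervals["start"]).to_numpy(),
        pd.to_datetime(intervals["end"]).to_numpy(),
    ):
        mask |= (ts >= start) & (ts < end)
    return mask


def apply_sleep(
    stream: EpochStream,
    sleep_intervals: pd.DataFrame | None,
    nonwear_intervals: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Per-epoch wear mask with precedence nonwear > asleep > awake.

    `sleep_intervals` has columns start, end (half-open timestamps);
    overlapping intervals raise :class:`EpochStreamError`.
    """
    mask = np.full(len(stream), WORN_AWAKE, dtype=np.int8)
    if sleep_intervals is not None and len(sleep_intervals):
        iv = sleep_intervals.copy()
        iv["start"] = pd.to_datetime(iv["start"])
        iv["end"] = pd.to_datetime(iv["end"])
        if (iv["start"] >= iv["end"]).any():
            raise EpochStreamError("sleep interval with start >= end")
        iv = iv.sort_values("start")
        if (iv["start"].iloc[1:].to_numpy() < iv["end"].iloc[:-1].to_numpy()).any():
            raise EpochStreamError(
                f"overlapping sleep intervals for child {stream.child_id}"
            )
        mask[_interval_mask(stream.timestamps, iv)] = WORN_ASLEEP
    for i0, i1 in nonwear_intervals or ():
        mask[i0:i1] = NONWEAR
    return mask


def classify_epoch(x_count):
    """Sedentary (True) iff the awake epoch's x-count is <= the cut-point."""
    return np.asarray(x_count) <= CUTPOINT


def summarize_days(
    stream: EpochStream,
    mask: np.ndarray,
    school_calendar: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate one stream into per-day records.

    Returns columns child_id, date, awake_minutes (T), sedentary_minutes
    (S), pct_sedentary (Y = 100*S/T), weekday_flag, school_day_flag,
    valid_flag. Days with no awake time get Y = NaN and valid_flag False
    (refined later by :func:`filter_valid`).
    """
    if len(mask) != len(stream):
        raise EpochStreamError("wear mask not aligned to stream")
    df = pd.DataFrame(
        {
            "date": stream.timestamps.dt.normalize(),
            "awake": mask == WORN_AWAKE,
            "sedentary": (mask == WORN_AWAKE) & classify_epoch(stream.counts("x")),
        }
    )
    grouped = df.groupby("date", sort=True)[["awake", "sedentary"]].sum()
    out = pd.DataFrame(
        {
            "child_id": stream.child_id,
            "date": grouped.index,
            "awake_minutes": grouped["awake"].to_numpy() / EPOCHS_PER_MINUTE,
            "sedentary_minutes": grouped["sedentary"].to_numpy() / EPOCHS_PER_MINUTE,
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_sedentary"] = 100.0 * out["sedentary_minutes"] / out["awake_minutes"]
    out["weekday_flag"] = out["date"].dt.dayofweek < 5
    if school_calendar is not None:
        cal = school_calendar.copy()
        cal["date"] = pd.to_datetime(cal["date"]).dt.normalize()
        is_school = out["date"].map(cal.set_index("date")["is_school_day"])
        out["school_day_flag"] = (is_school.fillna(False).astype(bool)) & out["weekday_flag"]
    else:
        out["school_day_flag"] = out["weekday_flag"]
    out["valid_flag"] = out["awake_minutes"] > 0
    return out


def filter_valid(
    days: pd.DataFrame,
    min_minutes: float = 600.0,
    min_weekdays: int = 3,
    min_weekend_days: int = 1,
    profile: Literal["default", "strict"] = "default",
) -> pd.DataFrame:
    """Apply day- and child-level inclusion criteria.

    Default profile: a day needs >= 600 awake minutes; a child is kept
    only if the surviving days include >= 3 weekdays and >= 1 weekend
    day. Strict profile: >= 720 minutes and >= 5 surviving days in total
    (no weekday/weekend split). Exclusion is all-or-none per child.
    """
    if profile == "strict":
        min_minutes, min_total_days = 720.0, 5
    elif profile != "default":
        raise ValueError(f"unknown validity profile {profile!r}")
    kept = days[days["awake_minutes"] >= min_minutes].copy()
    if len(kept) == 0:
        return kept
    def child_ok(group: pd.DataFrame) -> bool:
        if profile == "strict":
            return len(group) >= min_total_days
        n_weekday = int(group["weekday_flag"].sum())
        n_weekend = int((~group["weekday_flag"]).sum())
        return n_weekday >= min_weekdays and n_weekend >= min_weekend_days
    ok_children = [cid for cid, g in kept.groupby("child_id") if child_ok(g)]
    out = kept[kept["child_id"].isin(ok_children)].reset_index(drop=True)
    out["valid_flag"] = True
    return out


def process_stream(
    stream: EpochStream,
    sleep_intervals: pd.DataFrame | None = None,
    school_calendar: pd.DataFrame | None = None,
    signal: Literal["x_axis", "vector_magnitude"] = "x_axis",
    min_run_minutes: int = 20,
) -> pd.DataFrame:
    """Full chain for one stream: non-wear -> mask -> day records."""
    nonwear = detect_nonwear(stream, signal=signal, min_run_minutes=min_run_minutes)
    mask = apply_sleep(stream, sleep_intervals, nonwear)
    return summarize_days(stream, mask, school_calendar)
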