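"""Per-minute contralateral differentials and daily per-location averages.

The measurement pipeline: for every minute where both socks are worn, the
right-minus-left temperature difference is computed at each of the 6 plantar
sites; daily averages of the absolute differential are then taken per site.
Minutes with one-sided wear are dropped, not imputed — a single-sided
reading has no contralateral reference.

Differentials are exchanged between stages as data frames:

``minute_differentials`` -> columns ``patient_id, day, minute, location,
delta, abs_delta`` (``delta`` signed right - left).

``daily_averages`` -> columns ``patient_id, day, location, mean_abs_delta,
n_minutes``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StatsError, UnsupportedStreamError
from .stream_io import LOCATIONS, MINUTES_PER_DAY, PatientStream

MINUTE_DIFF_COLUMNS = ["patient_id", "day", "minute", "location", "delta", "abs_delta"]
DAILY_DIFF_COLUMNS = ["patient_id", "day", "location", "mean_abs_delta", "n_minutes"]


@dataclass(frozen=True)
class MinuteDifferential:
    """One minute's right-minus-left differential at one location."""

    day: int
    minute: int
    location: str
    delta: float
    abs_delta: float


@dataclass(frozen=True)
class DailyDifferential:
    """Per-patient, per-day, per-location mean absolute differential."""

    patient_id: str
    day: int
    location: str
    mean_abs_delta: float
    n_minutes: int


def minute_differentials(stream: PatientStream) -> pd.DataFrame:
    """Right-minus-left differential per bilaterally worn minute and location.

    Emits 6 rows (one per location) for every minute where both feet are
    worn; other minutes are skipped, not zero-filled. Streams where exactly
    one foot is ever worn are unsupported (no contralateral reference).
    """
    left_ever = bool(stream.worn[:, 0].any()) if len(stream) else False
    right_ever = bool(stream.worn[:, 1].any()) if len(stream) else False
    if left_ever != right_ever:
        missing = "right" if left_ever else "left"
        raise UnsupportedStreamError(
            f"patient {stream.patient_id}: {missing} foot never worn — "
            "unilateral streams are unsupported"
        )
    mask = stream.bilateral_worn
    day = stream.day[mask]
    minute = stream.minute[mask]
    delta = stream.temps[mask, 1, :] - stream.temps[mask, 0, :]  # right - left
    n = len(day)
    return pd.DataFrame(
        {
            "patient_id": np.repeat(stream.patient_id, n * 6),
            "day": np.repeat(day, 6),
            "minute": np.repeat(minute, 6),
            "location": np.tile(np.array(LOCATIONS), n),
            "delta": delta.ravel(),
            "abs_delta": np.abs(delta).ravel(),
        }
    )


def daily_averages(diffs: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute differential per (patient, day, location).

    Averages are over that day's bilaterally worn minutes only, unweighted;
    days with no bilateral minutes simply produce no row.
    """
    if len(diffs) == 0:
        return pd.DataFrame(columns=DAILY_DIFF_COLUMNS)
    out = (
        diffs.groupby(["patient_id", "day", "location"], as_index=False, sort=True)
        .agg(mean_abs_delta=("abs_delta", "mean"), n_minutes=("abs_delta", "size"))
    )
    return out[DAILY_DIFF_COLUMNS]


def patient_window_statistic(
    diffs: pd.DataFrame, window, method: str = "pooled"
) -> float:
    """Single scalar per patient-window: the mean absolute differential.

    ``method="pooled"`` (primary) weights every retained minute-location
    reading equally. ``method="daily"`` first averages per (day, location),
    then averages the daily means — exposed because the source protocol is
    ambiguous about the aggregation order.
    """
    if method not in ("pooled", "daily"):
        raise ValueError(f"unknown method {method!r}")
    keys = np.fromiter(
        (d * MINUTES_PER_DAY + m for d, m in window.minutes), dtype=np.int64
    )
    if len(keys) == 0:
        raise StatsError("empty analysis window")
    row_key = diffs["day"].to_numpy() * MINUTES_PER_DAY + diffs["minute"].to_numpy()
    sel = diffs[np.isin(row_key, keys)]
    if len(sel) == 0:
        raise StatsError(
            "analysis window minutes not present in the differential table"
        )
    if method == "pooled":
        return float(sel["abs_delta"].mean())
    per_day = sel.groupby(["day", "location"])["abs_delta"].mean()
    return float(per_day.mean())
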