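"""Data model, readers/writers, and validation for bilateral temperature streams.

A stream holds one record per monitored minute: 12 temperatures (2 feet x 6
plantar sites) plus a per-foot worn flag. On disk, streams are stored either
as long-format CSV (one sensor reading per row) or as a compact JSONL
variant (one minute per line). Temperatures are degrees Fahrenheit
throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import (
    StreamFormatError,
    StreamValidationError,
)

FEET: tuple[str, ...] = ("left", "right")
LOCATIONS: tuple[str, ...] = ("hallux", "heel", "arch", "mts1", "mts3", "mts5")

FOOT_INDEX: dict[str, int] = {f: i for i, f in enumerate(FEET)}
LOCATION_INDEX: dict[str, int] = {l: i for i, l in enumerate(LOCATIONS)}

#: physiological + ambient sanity band for any reading, in deg F
TEMP_MIN = 32.0
TEMP_MAX = 120.0

STREAM_CSV_HEADER = ["patient_id", "day", "minute", "foot", "location", "temp_f", "worn"]

MINUTES_PER_DAY = 1440


@dataclass
class MinuteRecord:
    """One minute of bilateral readings: 12 temperatures plus worn flags."""

    day: int
    minute: int
    temps: Mapping[tuple[str, str], float]  # (foot, location) -> deg F
    worn: Mapping[str, bool]  # foot -> worn

    def validate(self) -> None:
        if not (0 <= self.minute < MINUTES_PER_DAY):
            raise StreamValidationError(
                f"minute {self.minute} outside [0, {MINUTES_PER_DAY})"
            )
        expected = {(f, l) for f in FEET for l in LOCATIONS}
        if set(self.temps) != expected:
            raise StreamValidationError(
                f"day {self.day} minute {self.minute}: expected exactly 12 "
                f"(foot, location) temperature slots, got {sorted(self.temps)}"
            )
        for key, t in self.temps.items():
            if not np.isfinite(t) or not (TEMP_MIN <= t <= TEMP_MAX):
                raise StreamValidationError(
                    f"day {self.day} minute {self.minute} {key}: temperature "
                    f"{t} outside [{TEMP_MIN}, {TEMP_MAX}]"
                )
        if set(self.worn) != set(FEET):
            raise StreamValidationError("worn flags must cover both feet")


@dataclass
class PatientStream:
    """Time-ordered minute records for one patient.

    Stored columnar for efficiency: ``temps[i, fi, li]`` is the reading at
    record ``i`` for foot index ``fi`` (left=0, right=1) and location index
    ``li`` (order of :data:`LOCATIONS`).
    """

    patient_id: str
    day: np.ndarray  # (n,) int
    minute: np.ndarray  # (n,) int
    temps: np.ndarray  # (n, 2, 6) float
    worn: np.ndarray  # (n, 2) bool

    def __len__(self) -> int:
        return len(self.day)

    @property
    def bilateral_worn(self) -> np.ndarray:
        """Boolean mask of minutes where both feet are worn."""
        return self.worn.all(axis=1)

    def record(self, i: int) -> MinuteRecord:
        temps = {
            (f, l): float(self.temps[i, fi, li])
            for f, fi in FOOT_INDEX.items()
            for l, li in LOCATION_INDEX.items()
        }
        worn = {f: bool(self.worn[i, fi]) for f, fi in FOOT_INDEX.items()}
        return MinuteRecord(int(self.day[i]), int(self.minute[i]), temps, worn)

    def iter_records(self) -> Iterator[MinuteRecord]:
        for i in range(len(self)):
            yield self.record(i)

    @classmethod
    def from_records(cls, patient_id: str, records: Iterable[MinuteRecord]) -> "PatientStream":
        records = list(records)
        n = len(records)
        day = np.empty(n, dtype=np.int64)
        minute = np.empty(n, dtype=np.int64)
        temps = np.empty((n, 2, 6), dtype=np.float64)
        worn = np.empty((n, 2), dtype=bool)
        for i, r in enumerate(records):
            day[i] = r.day
            minute[i] = r.minute
            for (f, l), t in r.temps.items():
                temps[i, FOOT_INDEX[f], LOCATION_INDEX[l]] = t
            for f, w in r.worn.items():
                worn[i, FOOT_INDEX[f]] = w
        stream = cls(patient_id, day, minute, temps, worn)
        stream.sort()
        stream.validate()
        return stream

    def sort(self) -> None:
        """Sort records by (day, minute) in place."""
        order = np.lexsort((self.minute, self.day))
        self.day = self.day[order]
        self.minute = self.minute[order]
        self.temps = self.temps[order]
        self.worn = self.worn[order]

    def validate(self) -> None:
        """Check ordering, uniqueness, and the temperature sanity band."""
        key = self.day * MINUTES_PER_DAY + self.minute
        if len(key) > 1 and not (np.diff(key) > 0).all():
            bad = int(np.flatnonzero(np.diff(key) <= 0)[0]) + 1
            raise StreamValidationError(
                f"records not strictly increasing at index {bad} "
                f"(day {int(self.day[bad])}, minute {int(self.minute[bad])})"
            )
        if (self.minute < 0).any() or (self.minute >= MINUTES_PER_DAY).any():
            raise StreamValidationError("minute-of-day outside [0, 1440)")
        if not np.isfinite(self.temps).all():
            raise StreamValidationError("non-finite temperature reading")
        if (self.temps < TEMP_MIN).any() or (self.temps > TEMP_MAX).any():
            raise StreamValidationError(
                f"temperature outside sanity band [{TEMP_MIN}, {TEMP_MAX}]"
            )


def _long_frame(stream: PatientStream, worn_only: bool = False) -> pd.DataFrame:
    mask = stream.worn.any(axis=1) if worn_only else np.ones(len(stream), dtype=bool)
    day = stream.day[mask]
    minute = stream.minute[mask]
    temps = stream.temps[mask]
    worn = stream.worn[mask]
    n = len(day)
    # row order: for each minute, left x 6 locations then right x 6 locations
    foot = np.tile(np.repeat(np.array(FEET), len(LOCATIONS)), n)
    location = np.tile(np.array(LOCATIONS), 2 * n)
    return pd.DataFrame(
        {
            "patient_id": np.repeat(stream.patient_id, 12 * n),
            "day": np.repeat(day, 12),
            "minute": np.repeat(minute, 12),
            "foot": foot,
            "location": location,
            "temp_f": temps.reshape(n, 12).ravel(),
            "worn": np.repeat(worn, 6, axis=1).reshape(n, 12).ravel(),
        }
    )


def write_stream(
    stream: PatientStream,
    path: str | Path,
    format: str = "csv",
    worn_only: bool = False,
) -> None:
    """Write a stream to ``path`` in ``csv`` or ``jsonl`` format.

    ``worn_only`` drops minutes where neither sock is worn (ambient
    readings), which shrinks files considerably without affecting any
    downstream differential.
    """
    path = Path(path)
    if format == "csv":
        frame = _long_frame(stream, worn_only=worn_only)
        frame["worn"] = np.where(frame["worn"], "true", "false")
        frame.to_csv(path, index=False)
    elif format == "jsonl":
        mask = stream.worn.any(axis=1) if worn_only else np.ones(len(stream), dtype=bool)
        with open(path, "w") as fh:
            fh.write(json.dumps({"patient_id": stream.patient_id}) + "\n")
            for i in np.flatnonzero(mask):
                obj = {
                    "day": int(stream.day[i]),
                    "minute": int(stream.minute[i]),
                    "worn": [bool(w) for w in stream.worn[i]],
                    "temps": [[float(t) for t in stream.temps[i, fi]] for fi in range(2)],
                }
                fh.write(json.dumps(obj) + "\n")
    else:
        raise ValueError(f"unknown stream format: {format!r}")


def _read_stream_csv(path: Path) -> PatientStream:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise StreamFormatError(str(exc)) from exc
    if list(frame.columns) != STREAM_CSV_HEADER:
        raise StreamFormatError(
            f"bad header {list(frame.columns)}, expected {STREAM_CSV_HEADER}", line=1
        )
    # +2: 1-based lines, header occupies line 1
    for col in ("day", "minute"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            raise StreamFormatError(
                f"non-integer {col} value {frame[col][vals.isna()].iloc[0]!r}",
                line=int(vals.index[vals.isna()][0]) + 2,
            )
        frame[col] = vals.astype(np.int64)
    # astype (unlike to_numeric's fast path) parses floats correctly rounded,
    # which the bit-exact round-trip contract needs
    try:
        frame["temp_f"] = frame["temp_f"].astype(np.float64)
    except ValueError:
        probe = pd.to_numeric(frame["temp_f"], errors="coerce")
        raise StreamFormatError(
            f"non-numeric temp_f value {frame['temp_f'][probe.isna()].iloc[0]!r}",
            line=int(probe.index[probe.isna()][0]) + 2,
        ) from None
    bad_worn = ~frame["worn"].isin(["true", "false"])
    if bad_worn.any():
        raise StreamFormatError(
            f"worn flag must be 'true' or 'false', got {frame['worn'][bad_worn].iloc[0]!r}",
            line=int(frame.index[bad_worn][0]) + 2,
        )
    frame["worn"] = frame["worn"] == "true"

    bad_loc = ~frame["location"].isin(LOCATIONS)
    if bad_loc.any():
        raise StreamValidationError(
            f"unknown location label {frame['location'][bad_loc].iloc[0]!r} "
            f"(expected one of {LOCATIONS})"
        )
    bad_foot = ~frame["foot"].isin(FEET)
    if bad_foot.any():
        raise StreamValidationError(
            f"unknown foot label {frame['foot'][bad_foot].iloc[0]!r}"
        )
    ids = frame["patient_id"].unique()
    if len(ids) != 1:
        raise StreamValidationError(
            f"stream file must contain a single patient, found {sorted(ids)}"
        )

    if frame.duplicated(["day", "minute", "foot", "location"]).any():
        dup = frame[frame.duplicated(["day", "minute", "foot", "location"])].iloc[0]
        raise StreamValidationError(
            f"duplicate reading at day {dup['day']} minute {dup['minute']} "
            f"{dup['foot']}/{dup['location']}"
        )
    return _frame_to_stream(str(ids[0]), frame)


def _frame_to_stream(patient_id: str, frame: pd.DataFrame) -> PatientStream:
    key = frame["day"].to_numpy() * MINUTES_PER_DAY + frame["minute"].to_numpy()
    uniq, inv = np.unique(key, return_inverse=True)
    counts = np.bincount(inv)
    if (counts != 12).any():
        i = int(np.flatnonzero(counts != 12)[0])
        raise StreamValidationError(
            f"day {uniq[i] // MINUTES_PER_DAY} minute {uniq[i] % MINUTES_PER_DAY}: "
            f"expected 12 sensor readings, found {int(counts[i])}"
        )
    n = len(uniq)
    fi = frame["foot"].map(FOOT_INDEX).to_numpy()
    li = frame["location"].map(LOCATION_INDEX).to_numpy()
    temps = np.empty((n, 2, 6), dtype=np.float64)
    temps[inv, fi, li] = frame["temp_f"].to_numpy()
    worn = np.zeros((n, 2), dtype=bool)
    # consistency: all 6 rows of a foot-minute must agree on worn
    worn_sum = np.zeros((n, 2), dtype=np.int64)
    np.add.at(worn_sum, (inv, fi), frame["worn"].to_numpy().astype(np.int64))
    if ((worn_sum != 0) & (worn_sum != 6)).any():
        i, f = [int(v[0]) for v in np.nonzero((worn_sum != 0) & (worn_sum != 6))]
        raise StreamValidationError(
            f"inconsistent worn flags at day {uniq[i] // MINUTES_PER_DAY} "
            f"minute {uniq[i] % MINUTES_PER_DAY} foot {FEET[f]}"
        )
    worn[worn_sum == 6] = True
    stream = PatientStream(
        patient_id=patient_id,
        day=(uniq // MINUTES_PER_DAY).astype(np.int64),
        minute=(uniq % MINUTES_PER_DAY).astype(np.int64),
        temps=temps,
        worn=worn,
    )
    stream.validate()
    return stream


def _read_stream_jsonl(path: Path) -> PatientStream:
    days, minutes, temps, worn = [], [], [], []
    patient_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(f"invalid JSON: {exc}", line=lineno) from exc
            if lineno == 1:
                if "patient_id" not in obj:
                    raise StreamFormatError(
                        "first line must be the patient header", line=1
                    )
                patient_id = str(obj["patient_id"])
                continue
            try:
                days.append(int(obj["day"]))
                minutes.append(int(obj["minute"]))
                worn.append([bool(w) for w in obj["worn"]])
                temps.append([[float(t) for t in foot] for foot in obj["temps"]])
            except (KeyError, TypeError, ValueError) as exc:
                raise StreamFormatError(f"bad minute object: {exc}", line=lineno) from exc
            if len(temps[-1]) != 2 or any(len(foot) != 6 for foot in temps[-1]):
                raise StreamFormatError("temps must be 2 feet x 6 locations", line=lineno)
    if patient_id is None:
        raise StreamFormatError("empty stream file", line=1)
    n = len(days)
    stream = PatientStream(
        patient_id=patient_id,
        day=np.asarray(days, dtype=np.int64),
        minute=np.asarray(minutes, dtype=np.int64),
        temps=np.asarray(temps, dtype=np.float64).reshape(n, 2, 6),
        worn=np.asarray(worn, dtype=bool).reshape(n, 2),
    )
    key = stream.day * MINUTES_PER_DAY + stream.minute
    if len(np.unique(key)) != n:
        raise StreamValidationError("duplicate (day, minute) timestamp")
    stream.sort()
    stream.validate()
    return stream


def read_stream(path: str | Path, format: str = "csv") -> PatientStream:
    """Read and validate a stream file. Rows need not be sorted on disk."""
    path = Path(path)
    if format == "csv":
        return _read_stream_csv(path)
    if format == "jsonl":
        return _read_stream_jsonl(path)
    raise ValueError(f"unknown stream format: {format!r}")


def wear_days(stream: PatientStream, min_minutes_per_day: int = 30) -> int:
    """Number of distinct days with >= ``min_minutes_per_day`` bilaterally worn minutes.

    A differential needs both feet, so a day counts only toward minutes where
    both socks are worn.
    """
    if min_minutes_per_day < 1:
        raise ValueError("min_minutes_per_day must be >= 1")
    if len(stream) == 0:
        return 0
    days = stream.day[stream.bilateral_worn]
    if len(days) == 0:
        return 0
    _, counts = np.unique(days, return_counts=True)
    return int((counts >= min_minutes_per_day).sum())


def filter_eligible(
    registry: list,
    streams: Mapping[str, PatientStream],
    min_wear_days: int = 50,
    min_minutes_per_day: int = 30,
) -> list:
    """Retain patients with strictly more than ``min_wear_days`` wear days.

    The comparison is strict (``>``), matching the protocol's inclusion rule.
    """
    missing = [p.patient_id for p in registry if p.patient_id not in streams]
    if missing:
        raise StreamValidationError(f"no stream for patient(s): {missing}")
    return [
        p
        for p in registry
        if wear_days(streams[p.patient_id], min_minutes_per_day) > min_wear_days
    ]
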