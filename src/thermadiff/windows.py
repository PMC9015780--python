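"""Analysis-window extraction and baseline / pre-injury / active segmentation.

The protocol analyses a 15-day window containing exactly 900 monitored
minutes: for injured patients the 15 days ending the day before diagnosis,
for controls a randomly selected 15-day span. How the 900 minutes were
picked within the window is not documented, so two modes are provided and
labelled in the output: uniform seeded subsampling of bilaterally worn
minutes (primary, applied to both cohorts for symmetry) and a fixed
per-day quota (900/15 = 60 is suggestive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import WindowError
from .stream_io import MINUTES_PER_DAY, PatientStream
from .synthetic import InjurySpec


@dataclass(frozen=True)
class AnalysisWindow:
    """A labelled day span plus the exact minutes retained for analysis."""

    patient_id: str
    label: str  # pre_injury | control_random | baseline | active
    start_day: int
    end_day: int
    minutes: tuple[tuple[int, int], ...]  # (day, minute) pairs, sorted
    sampling: str = "uniform"  # uniform | per_day_quota

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "label": self.label,
            "start_day": self.start_day,
            "end_day": self.end_day,
            "sampling": self.sampling,
            "minutes": [list(m) for m in self.minutes],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "AnalysisWindow":
        return cls(
            patient_id=obj["patient_id"],
            label=obj["label"],
            start_day=int(obj["start_day"]),
            end_day=int(obj["end_day"]),
            minutes=tuple((int(d), int(m)) for d, m in obj["minutes"]),
            sampling=obj.get("sampling", "uniform"),
        )


@dataclass(frozen=True)
class PeriodSegmentation:
    """Disjoint, ordered day ranges: baseline < pre_injury < active."""

    patient_id: str
    baseline: tuple[int, int]
    pre_injury: tuple[int, int]
    active: Optional[tuple[int, int]]


def _worn_keys_in_span(stream: PatientStream, start_day: int, end_day: int) -> np.ndarray:
    """Sorted (day*1440 + minute) keys of bilaterally worn minutes in the span."""
    mask = stream.bilateral_worn & (stream.day >= start_day) & (stream.day <= end_day)
    return stream.day[mask] * MINUTES_PER_DAY + stream.minute[mask]


def _sample_minutes(
    keys: np.ndarray,
    days_of: np.ndarray,
    minutes_budget: int,
    days: int,
    rng: np.random.Generator,
    per_day_quota: Optional[int],
) -> np.ndarray:
    if per_day_quota is not None:
        if per_day_quota * days != minutes_budget:
            raise WindowError(
                f"per-day quota {per_day_quota} x {days} days != budget {minutes_budget}"
            )
        chosen = []
        for day in np.unique(days_of):
            day_keys = keys[days_of == day]
            if len(day_keys) < per_day_quota:
                raise WindowError(
                    f"day {day} has {len(day_keys)} bilateral minutes, "
                    f"quota needs {per_day_quota}"
                )
            chosen.append(rng.choice(day_keys, size=per_day_quota, replace=False))
        if len(chosen) < days:
            raise WindowError(
                f"only {len(chosen)} of {days} window days have any bilateral minutes"
            )
        picked = np.concatenate(chosen)
    else:
        if len(keys) < minutes_budget:
            raise WindowError(
                f"window has {len(keys)} bilaterally worn minutes, "
                f"{minutes_budget} required (short by {minutes_budget - len(keys)})"
            )
        if len(keys) == minutes_budget:
            picked = keys
        else:
            picked = rng.choice(keys, size=minutes_budget, replace=False)
    return np.sort(picked)


def _keys_to_minutes(keys: np.ndarray) -> tuple[tuple[int, int], ...]:
    return tuple(
        (int(k // MINUTES_PER_DAY), int(k % MINUTES_PER_DAY)) for k in keys
    )


def extract_preinjury_window(
    stream: PatientStream,
    diagnosis_day: int,
    minutes_budget: int = 900,
    days: int = 15,
    seed: int = 0,
    per_day_quota: Optional[int] = None,
) -> AnalysisWindow:
    """The ``days``-day window ending the day before diagnosis.

    Exactly ``minutes_budget`` bilaterally worn minutes are retained,
    subsampled uniformly without replacement with the given seed (all
    retained if supply equals the budget). Deterministic given
    (stream, parameters, seed).
    """
    if diagnosis_day < days:
        raise WindowError(
            f"diagnosis day {diagnosis_day} leaves no room for a {days}-day window"
        )
    start_day, end_day = diagnosis_day - days, diagnosis_day - 1
    keys = _worn_keys_in_span(stream, start_day, end_day)
    rng = np.random.default_rng(seed)
    picked = _sample_minutes(
        keys, keys // MINUTES_PER_DAY, minutes_budget, days, rng, per_day_quota
    )
    return AnalysisWindow(
        patient_id=stream.patient_id,
        label="pre_injury",
        start_day=start_day,
        end_day=end_day,
        minutes=_keys_to_minutes(picked),
        sampling="per_day_quota" if per_day_quota is not None else "uniform",
    )


def sample_control_window(
    stream: PatientStream,
    minutes_budget: int = 900,
    days: int = 15,
    seed: int = 0,
    per_day_quota: Optional[int] = None,
) -> AnalysisWindow:
    """A randomly selected eligible ``days``-day span with sampled minutes.

    Eligibility of each candidate span is recomputed from the bilateral-wear
    record (>= budget worn minutes, or the per-day quota everywhere); one
    eligible span is chosen uniformly, then minutes are sampled as in
    :func:`extract_preinjury_window`.
    """
    if len(stream) == 0:
        raise WindowError("empty stream")
    rng = np.random.default_rng(seed)
    last_day = int(stream.day.max())
    if last_day + 1 < days:
        raise WindowError(f"stream spans fewer than {days} days")

    worn_days = stream.day[stream.bilateral_worn]
    per_day = np.bincount(worn_days, minlength=last_day + 1)
    window_counts = np.convolve(per_day, np.ones(days, dtype=np.int64), "valid")
    if per_day_quota is not None:
        ok_days = per_day >= per_day_quota
        eligible = (
            np.convolve(ok_days.astype(np.int64), np.ones(days, dtype=np.int64), "valid")
            == days
        )
    else:
        eligible = window_counts >= minutes_budget
    candidates = np.flatnonzero(eligible)
    if len(candidates) == 0:
        raise WindowError(
            f"no {days}-day span with {minutes_budget} bilaterally worn minutes"
        )
    start_day = int(candidates[rng.integers(len(candidates))])
    end_day = start_day + days - 1
    keys = _worn_keys_in_span(stream, start_day, end_day)
    picked = _sample_minutes(
        keys, keys // MINUTES_PER_DAY, minutes_budget, days, rng, per_day_quota
    )
    return AnalysisWindow(
        patient_id=stream.patient_id,
        label="control_random",
        start_day=start_day,
        end_day=end_day,
        minutes=_keys_to_minutes(picked),
        sampling="per_day_quota" if per_day_quota is not None else "uniform",
    )


def segment_periods(
    stream: PatientStream, injury: Optional[InjurySpec], days: int = 15
) -> PeriodSegmentation:
    """Partition the record into baseline / pre-injury / active day ranges.

    baseline = [0, diagnosis - days - 1], pre-injury = the ``days`` days
    before diagnosis, active = [diagnosis, last day]. Requires a non-empty
    baseline, i.e. diagnosis on day >= days + 1.
    """
    if injury is None:
        raise WindowError(
            f"patient {stream.patient_id} has no injury; segmentation is "
            "only defined for injured patients"
        )
    d = injury.diagnosis_day
    if d < days + 1:
        raise WindowError(
            f"diagnosis day {d} too early for a {days}-day pre-injury window "
            "with a non-empty baseline"
        )
    last_day = int(stream.day.max()) if len(stream) else d
    return PeriodSegmentation(
        patient_id=stream.patient_id,
        baseline=(0, d - days - 1),
        pre_injury=(d - days, d - 1),
        active=(d, last_day) if last_day >= d else None,
    )


def write_windows(windows: list[AnalysisWindow], path) -> None:
    with open(path, "w") as fh:
        json.dump([w.to_dict() for w in windows], fh, indent=2, sort_keys=True)


def read_windows(path) -> list[AnalysisWindow]:
    with open(path) as fh:
        return [AnalysisWindow.from_dict(obj) for obj in json.load(fh)]
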