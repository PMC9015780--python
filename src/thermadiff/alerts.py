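"""The >4 F daily alert rule and sustained-hotspot escalation.

Alerts are evaluated on daily averages, not raw minutes: monitoring review
is daily and minute-level spikes are noise-dominated. A location alerts on
a day when its mean absolute differential strictly exceeds the threshold
and enough minutes contributed; a run of consecutive alert days at the same
location reaching ``escalation_days`` escalates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class AlertConfig:
    threshold: float = 4.0
    escalation_days: int = 5
    min_minutes: int = 30

    def __post_init__(self):
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if self.escalation_days < 1:
            raise ConfigError("escalation_days must be >= 1")
        if self.min_minutes < 1:
            raise ConfigError("min_minutes must be >= 1")


@dataclass(frozen=True)
class AlertEvent:
    patient_id: str
    day: int
    location: str
    value: float  # the triggering daily mean_abs_delta
    consecutive_days: int
    escalated: bool


def evaluate_alerts(dailies: pd.DataFrame, config: AlertConfig = AlertConfig()) -> list[AlertEvent]:
    """One event per (patient, day, location) whose daily mean exceeds threshold.

    ``value > threshold`` is strict: a daily mean of exactly 4.0 F does not
    alert. Days with fewer than ``min_minutes`` contributing minutes are
    ineligible. ``consecutive_days`` is the length of the run of alert days
    at that location ending that day; a missing or non-alerting day breaks
    the run.
    """
    if len(dailies) == 0:
        return []
    events: list[AlertEvent] = []
    frame = dailies.sort_values(["patient_id", "location", "day"])
    for (pid, loc), group in frame.groupby(["patient_id", "location"], sort=True):
        run = 0
        prev_alert_day: Optional[int] = None
        for day, value, n_minutes in zip(
            group["day"], group["mean_abs_delta"], group["n_minutes"]
        ):
            if value > config.threshold and n_minutes >= config.min_minutes:
                run = run + 1 if prev_alert_day == day - 1 else 1
                prev_alert_day = int(day)
                events.append(
                    AlertEvent(
                        patient_id=pid,
                        day=int(day),
                        location=loc,
                        value=float(value),
                        consecutive_days=run,
                        escalated=run >= config.escalation_days,
                    )
                )
    events.sort(key=lambda e: (e.patient_id, e.day, e.location))
    return events


def first_alert_day(events: Sequence[AlertEvent], patient_id: str) -> Optional[int]:
    """Earliest alert day for the patient, or None if they never alerted."""
    days = [e.day for e in events if e.patient_id == patient_id]
    return min(days) if days else None


def events_frame(events: Sequence[AlertEvent]) -> pd.DataFrame:
    """Alert events as a data frame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "day": e.day,
                "location": e.location,
                "value": e.value,
                "consecutive_days": e.consecutive_days,
                "escalated": e.escalated,
            }
            for e in events
        ],
        columns=["patient_id", "day", "location", "value", "consecutive_days", "escalated"],
    )
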